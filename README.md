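# indelgwas

A tested, reusable re-implementation of an indel-to-trait analysis pipeline
for a pig backcross design: multi-caller indel consensus with exact filter
accounting, functional-consequence and severity annotation, founder-frequency
candidate selection, and mixed-linear-model association with
Benjamini–Hochberg FDR — exercised end to end on synthetic data that emulates
the original study design (2 + 5 founders, three caller call-sets, three BC1
backcross populations, fatty-acid-style phenotypes).

## Modules

| module | role |
| --- | --- |
| `indelgwas.vario` | VCF I/O, canonical left-aligned minimal indel keys |
| `indelgwas.syndata` | seeded generators: genome + gene models, truth variants, founders, noisy caller call-sets, backcross gene-drop, phenotypes |
| `indelgwas.consensus` | three-caller intersection, 2-of-3 genotype majority, multi-alt and fixed-alt filters, exact ledger accounting, density/length summaries |
| `indelgwas.consequence` | consequence terms (frameshift/inframe/splice/UTR/flank/...), High–Moderate–Low–Modifier severity, HGVS-style protein changes |
| `indelgwas.assoc` | founder frequencies, candidate selection, marker QC (MAF < 5 %, missing > 5 %), centred kinship, REML null fit, EMMAX-style scan, BH-FDR |
| `indelgwas.pipeline` | one-command orchestration with a reproducible run manifest |

## CLI

```bash
indelgwas run-all --config config.yaml --out run/       # full pipeline
indelgwas simulate  --out run/sim                       # stages standalone:
indelgwas consensus --vcf a.vcf --vcf b.vcf --vcf c.vcf --fasta ref.fa --out run/cons
indelgwas annotate  --vcf cons.vcf --gff3 genes.gff3 --fasta ref.fa --out run/ann
indelgwas gwas      --genotypes g.tsv --phenotypes p.tsv --out run/gwas
indelgwas report    --manifest run/manifest.json
```

Every stage reads plain-text formats (FASTA, GFF3, VCF v4.2, TSV) written by
the previous stage, so stages are individually re-runnable; identical config
and seed reproduce byte-identical outputs.  `run-all` with no config uses a
built-in demo configuration (4 × 100 kb chromosomes, 2 + 5 founders, BC1
populations of 160/143/138) that plants one Moderate-severity coding indel
fixed in the sire breed and absent elsewhere, with a backcross-specific
effect, and shows it being selected and reaching suggestive FDR in the target
backcross only.

## Conventions

* Coordinates are 1-based; an indel's position is its anchor base (the base
  preceding the inserted/deleted run), VCF-style.  All caller representations
  are unified by left-alignment with minimal alleles.
* Genotype codes for association are +1 hom-ref, 0 het, −1 hom-alt
  (missing = NA, mean-imputed per marker for kinship and scan).
* Kinship is the centred relatedness matrix `K = (1/p) · Xc · Xcᵀ`.
* The scan fixes the variance ratio from a REML null fit and re-estimates the
  overall scale per marker (so a zero polygenic component reduces exactly to
  OLS); p-values use a t reference on residual degrees of freedom; FDR classes
  are significant (q ≤ 0.05) and suggestive (0.05 < q ≤ 0.1).

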