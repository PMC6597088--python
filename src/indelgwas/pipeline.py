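"""One-command orchestration: simulate -> consensus -> annotate -> select ->
associate, with a JSON run manifest for reproducibility.

Each stage reads its inputs from files written by the previous stage, so any
stage can be re-run standalone; re-running the whole pipeline with the same
config and seed reproduces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assoc, consensus as cns, vario
from .consequence import annotate_all
from .syndata import (
    CallerProfile,
    CrossDesign,
    PhenotypeModelConfig,
    generate_genome,
    plant_coding_indel,
    plant_truth_variants,
    simulate_backcross,
    simulate_callsets,
    simulate_founders,
    simulate_phenotypes,
)
from .syndata.genome import read_gff3, write_fasta, write_gff3

log = logging.getLogger(__name__)

DEFAULT_CONFIG = {
    "seed": 1,
    "genome": {"n_chromosomes": 4, "chrom_length": 100_000, "n_genes": 5},
    "variants": {
        "n_indels": 120,
        "n_snps": 400,
        "freq_spec": [[1.0, 0.0], [0.0, 0.8], [0.5, 0.5], [0.2, 0.6], [0.3, 0.3]],
        "deletion_fraction": 0.529,
    },
    "candidate": {
        "gene_index": 0,
        "freq_IB": 1.0,
        "freq_LD": 0.0,
        "effect": 0.25,
        "target_backcross": "BC1_PI",
    },
    "callers": [
        {"name": "callerA", "sensitivity": 0.97, "genotype_error_rate": 0.01,
         "representation_jitter_rate": 0.1, "false_positive_rate_per_mb": 2.0},
        {"name": "callerB", "sensitivity": 0.95, "genotype_error_rate": 0.01,
         "representation_jitter_rate": 0.1, "false_positive_rate_per_mb": 2.0},
        {"name": "callerC", "sensitivity": 0.96, "genotype_error_rate": 0.01,
         "representation_jitter_rate": 0.1, "false_positive_rate_per_mb": 2.0},
    ],
    "design": {
        "n_founder_sires_IB": 2,
        "n_founder_dams_LD": 5,
        "backcrosses": [["BC1_LD", "LD", 160], ["BC1_DU", "DU", 143], ["BC1_PI", "PI", 138]],
        "recombination_rate": 1.0,
    },
    "phenotype": {
        "trait_name": "trait", "trait_mean": 0.51, "trait_sd": 0.14,
        "h2_polygenic": 0.3,
    },
    "association": {"maf_min": 0.05, "missing_max": 0.05},
    "lipid_genes": ["gene1"],
}

_SCHEMA_KEYS = {
    "seed", "genome", "variants", "candidate", "callers", "design",
    "phenotype", "association", "lipid_genes", "outdir",
}


class ConfigError(ValueError):
    pass


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            cfg = yaml.safe_load(fh)
    else:
        cfg = dict(path_or_dict)
    unknown = set(cfg) - _SCHEMA_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    merged = json.loads(json.dumps(DEFAULT_CONFIG))
    for k, v in cfg.items():
        if isinstance(v, dict) and isinstance(merged.get(k), dict):
            merged[k].update(v)
        else:
            merged[k] = v
    for key in ("genome", "variants", "design"):
        if not isinstance(merged[key], dict):
            raise ConfigError(f"config section {key!r} must be a mapping")
    if len(merged["callers"]) < 2:
        raise ConfigError("need at least two caller profiles")
    return merged


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True).encode()
    ).hexdigest()[:16]


def _stage_seed(root: int, stage: int) -> int:
    return int(np.random.SeedSequence([root, stage]).generate_state(1)[0])


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def stage_simulate(cfg: dict, outdir: Path) -> dict:
    seed = cfg["seed"]
    outdir.mkdir(parents=True, exist_ok=True)
    genome = generate_genome(seed=_stage_seed(seed, 0), **cfg["genome"])
    write_fasta(genome, outdir / "genome.fa")
    write_gff3(genome.gene_models, outdir / "genes.gff3")

    vcfg = cfg["variants"]
    truth = plant_truth_variants(
        genome,
        n_indels=vcfg["n_indels"],
        n_snps=vcfg["n_snps"],
        freq_spec=[tuple(s) for s in vcfg["freq_spec"]],
        deletion_fraction=vcfg.get("deletion_fraction", 0.529),
        seed=_stage_seed(seed, 1),
    )
    planted = []
    ccfg = cfg.get("candidate")
    if ccfg and genome.gene_models:
        gene = genome.gene_models[ccfg.get("gene_index", 0)]
        cand = plant_coding_indel(
            genome, gene,
            freq_IB=ccfg.get("freq_IB", 1.0), freq_LD=ccfg.get("freq_LD", 0.0),
            planted_effect=ccfg.get("effect", 0.0), seed=_stage_seed(seed, 2),
        )
        # drop any colliding truth variant, then insert the candidate
        truth = [
            v for v in truth
            if v.key.chrom != cand.key.chrom or abs(v.key.pos - cand.key.pos) > 80
        ]
        truth.append(cand)
        truth.sort(key=lambda v: (v.key.chrom, v.key.pos))
        planted.append(
            (str(cand.key), ccfg.get("effect", 0.0), ccfg.get("target_backcross"))
        )

    design = CrossDesign(
        n_founder_sires_IB=cfg["design"]["n_founder_sires_IB"],
        n_founder_dams_LD=cfg["design"]["n_founder_dams_LD"],
        backcrosses=[tuple(b) for b in cfg["design"]["backcrosses"]],
        recombination_rate=cfg["design"]["recombination_rate"],
    )
    founders = simulate_founders(truth, design, seed=_stage_seed(seed, 3))
    profiles = [CallerProfile(**p) for p in cfg["callers"]]
    callsets = simulate_callsets(founders, genome, profiles, seed=_stage_seed(seed, 4))
    contigs = genome.lengths()
    vcf_paths = {}
    for name, records in callsets.items():
        path = outdir / f"calls.{name}.vcf"
        vario.write_vcf(records, path, sample_names=founders.names, contigs=contigs)
        vcf_paths[name] = str(path)

    bc = simulate_backcross(founders, genome, design, seed=_stage_seed(seed, 5))
    pheno = simulate_phenotypes(
        bc,
        assoc.centered_kinship(bc.codes),
        PhenotypeModelConfig(**cfg["phenotype"]),
        planted,
        seed=_stage_seed(seed, 6),
    )

    truth_df = pd.DataFrame(
        {
            "key": [str(v.key) for v in truth],
            "chrom": [v.key.chrom for v in truth],
            "pos": [v.key.pos for v in truth],
            "ref": [v.key.ref for v in truth],
            "alt": [v.key.alt for v in truth],
            "class": [v.variant_class for v in truth],
            "freq_IB": [v.true_freq_IB for v in truth],
            "freq_LD": [v.true_freq_LD for v in truth],
            "planted_effect": [v.planted_effect for v in truth],
        }
    )
    truth_df.to_csv(outdir / "truth.tsv", sep="\t", index=False)

    geno_df = pd.concat(
        [
            bc.individuals.reset_index(drop=True),
            pd.DataFrame(
                bc.codes, columns=[str(v.key) for v in bc.markers]
            ).reset_index(drop=True),
        ],
        axis=1,
    )
    geno_df.to_csv(outdir / "genotypes.tsv", sep="\t", index=False, na_rep="NA")
    bc.pedigree.to_csv(outdir / "pedigree.tsv", sep="\t", index=False)
    pheno.to_csv(outdir / "phenotypes.tsv", sep="\t", index=False)

    founder_df = founders.genotype_frame()
    founder_df.insert(0, "key", founder_df.index)
    founder_df.to_csv(outdir / "founder_genotypes.tsv", sep="\t", index=False)

    return {
        "fasta": str(outdir / "genome.fa"),
        "gff3": str(outdir / "genes.gff3"),
        "truth": str(outdir / "truth.tsv"),
        "vcfs": vcf_paths,
        "genotypes": str(outdir / "genotypes.tsv"),
        "phenotypes": str(outdir / "phenotypes.tsv"),
        "pedigree": str(outdir / "pedigree.tsv"),
        "founder_genotypes": str(outdir / "founder_genotypes.tsv"),
        "n_truth": len(truth),
        "planted": planted,
    }


def _load_genome_dict(fasta: str) -> dict:
    seqs: dict = {}
    name = None
    chunks: list = []
    with open(fasta) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            else:
                chunks.append(line)
    if name is not None:
        seqs[name] = "".join(chunks)
    return seqs


def stage_consensus(vcf_paths: dict, fasta: str, outdir: Path) -> dict:
    outdir.mkdir(parents=True, exist_ok=True)
    genome = _load_genome_dict(fasta)
    callsets = {
        name: list(vario.read_vcf(path, caller=name)) for name, path in vcf_paths.items()
    }
    variants, acc = cns.run_consensus(callsets, genome)
    kept = cns.retained(variants)
    sample_names = None
    for records in callsets.values():
        if records:
            sample_names = list(records[0].sample_names)
            break
    out_records = [
        vario.VariantRecord(
            chrom=v.key.chrom, pos=v.key.pos, ref=v.key.ref, alt=v.key.alt,
            genotypes=list(v.genotypes), caller="consensus",
            sample_names=tuple(sample_names or ()),
        )
        for v in kept
    ]
    vario.write_vcf(
        out_records, outdir / "consensus.vcf", sample_names=sample_names,
        contigs={c: len(s) for c, s in genome.items()},
    )
    with open(outdir / "accounting.json", "w") as fh:
        json.dump(acc.as_dict(), fh, indent=2, sort_keys=True)
    pd.DataFrame(
        [{"key": str(v.key), "fate": v.fate} for v in variants]
    ).to_csv(outdir / "fates.tsv", sep="\t", index=False)
    dens = cns.chromosome_density(variants, {c: s for c, s in genome.items()})
    pd.DataFrame(dens, columns=["chrom", "indels_per_mb"]).to_csv(
        outdir / "density.tsv", sep="\t", index=False
    )
    hist, del_frac = cns.length_spectrum(variants)
    pd.DataFrame(
        [
            {"class": cls, "length": length, "count": cnt}
            for (cls, length), cnt in sorted(hist.items())
        ]
    ).to_csv(outdir / "length_spectrum.tsv", sep="\t", index=False)
    return {
        "consensus_vcf": str(outdir / "consensus.vcf"),
        "accounting": acc.as_dict(),
        "deletion_fraction": del_frac,
    }


def stage_annotate(consensus_vcf: str, gff3: str, fasta: str, outdir: Path) -> dict:
    outdir.mkdir(parents=True, exist_ok=True)
    genome = _load_genome_dict(fasta)
    genes = read_gff3(gff3)
    result = vario.read_vcf(consensus_vcf, caller="consensus")
    keys = [vario.normalize(r, genome) for r in result]
    anns = annotate_all(keys, genes, genome)
    pd.DataFrame(
        [
            {
                "key": str(a.key),
                "gene": a.gene_id or "",
                "transcript": a.transcript_id or "",
                "terms": ",".join(sorted(a.terms)),
                "severity": a.severity,
                "protein_change": a.protein_change or "",
            }
            for a in anns
        ]
    ).to_csv(outdir / "annotations.tsv", sep="\t", index=False)
    return {"annotations": str(outdir / "annotations.tsv"), "n_annotations": len(anns)}


def stage_select(
    consensus_vcf: str, annotations_tsv: str, gff3: str, fasta: str,
    lipid_genes, outdir: Path,
) -> dict:
    outdir.mkdir(parents=True, exist_ok=True)
    genome = _load_genome_dict(fasta)
    genes = read_gff3(gff3)
    result = vario.read_vcf(consensus_vcf, caller="consensus")
    breeds = [s.split("_")[0] for s in result.samples]
    keys = [vario.normalize(r, genome) for r in result]
    geno = np.array(
        [[np.nan if g is None else g for g in r.genotypes] for r in result], dtype=float
    )
    freqs = assoc.founder_freqs(keys, geno, breeds)
    anns = annotate_all(keys, genes, genome)
    selected = assoc.select_candidates(freqs, anns, lipid_genes)
    fmap = {f.key: f for f in freqs}
    rows = []
    for key, criteria, ann in selected:
        f = fmap[key]
        rows.append(
            {
                "gene": (ann.gene_id or "") if ann else "",
                "chrom": key.chrom,
                "position": key.pos,
                "ref": key.ref,
                "alt": key.alt,
                "freq_IB": f.freq_IB,
                "freq_LD": f.freq_LD,
                "consequence": ",".join(sorted(ann.terms)) if ann else "",
                "severity": ann.severity if ann else "",
                "criteria": "".join(sorted(criteria)),
            }
        )
    pd.DataFrame(
        rows,
        columns=["gene", "chrom", "position", "ref", "alt", "freq_IB", "freq_LD",
                 "consequence", "severity", "criteria"],
    ).to_csv(outdir / "candidates.tsv", sep="\t", index=False)
    return {
        "candidates": str(outdir / "candidates.tsv"),
        "n_candidates": len(selected),
        "selected_keys": [str(k) for k, _, _ in selected],
    }


def load_genotype_matrix(path: str) -> assoc.GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", na_values="NA")
    meta_cols = ["id", "backcross", "sex", "batch"]
    markers = [c for c in df.columns if c not in meta_cols]
    return assoc.GenotypeMatrix(
        individuals=df[meta_cols].reset_index(drop=True),
        markers=markers,
        codes=df[markers].to_numpy(dtype=float),
    )


def stage_gwas(genotypes_tsv: str, phenotypes_tsv: str, cfg: dict, outdir: Path) -> dict:
    outdir.mkdir(parents=True, exist_ok=True)
    acfg = cfg.get("association", {})
    trait = cfg["phenotype"]["trait_name"]
    G = load_genotype_matrix(genotypes_tsv)
    pheno = pd.read_csv(phenotypes_tsv, sep="\t")
    pheno = pheno.set_index("id").loc[G.individuals["id"]].reset_index()

    Gq, qc_report = assoc.marker_qc(
        G, maf_min=acfg.get("maf_min", 0.05), missing_max=acfg.get("missing_max", 0.05)
    )
    genotype_freqs = assoc.genotype_freq_table(Gq)
    genotype_freqs.to_csv(outdir / "genotype_frequencies.tsv", sep="\t", index=False)

    summary = {"qc": qc_report, "scans": {}}
    scans = {"merged": None}
    for bc in dict.fromkeys(G.individuals["backcross"]):
        scans[bc] = bc
    for label, bc in scans.items():
        if bc is None:
            sub = np.ones(len(pheno), dtype=bool)
            include_bc = True
        else:
            sub = (pheno["backcross"] == bc).to_numpy()
            include_bc = False
        Gsub = assoc.GenotypeMatrix(
            individuals=Gq.individuals[sub].reset_index(drop=True),
            markers=Gq.markers,
            codes=Gq.codes[sub],
        )
        results, vc = assoc.scan_trait(
            pheno[sub].reset_index(drop=True), trait, Gsub,
            include_backcross=include_bc,
        )
        df = pd.DataFrame(
            [
                {
                    "marker": r.marker, "a_hat": r.a_hat, "se": r.se,
                    "statistic": r.statistic, "p_value": r.p_value,
                    "q_value": r.q_value, "class": r.cls,
                }
                for r in results
            ]
        )
        df.to_csv(outdir / f"assoc.{label}.tsv", sep="\t", index=False)
        summary["scans"][label] = {
            "n_markers": len(results),
            "n_significant": int((df["class"] == "significant").sum()) if len(df) else 0,
            "n_suggestive": int((df["class"] == "suggestive").sum()) if len(df) else 0,
            "sigma_u2": vc.sigma_u2,
            "sigma_e2": vc.sigma_e2,
        }
    return summary


def run_all(config, outdir=None) -> dict:
    """Execute all stages in order; returns the run manifest (also written to
    ``manifest.json`` in the output directory)."""
    cfg = load_config(config)
    outdir = Path(outdir or cfg.get("outdir", "indelgwas_run"))
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_hash": config_hash(cfg), "seed": cfg["seed"], "stages": {}}
    sim = stage_simulate(cfg, outdir / "sim")
    manifest["stages"]["simulate"] = sim
    cons = stage_consensus(sim["vcfs"], sim["fasta"], outdir / "consensus")
    manifest["stages"]["consensus"] = cons
    ann = stage_annotate(cons["consensus_vcf"], sim["gff3"], sim["fasta"], outdir / "annotate")
    manifest["stages"]["annotate"] = ann
    sel = stage_select(
        cons["consensus_vcf"], ann["annotations"], sim["gff3"], sim["fasta"],
        cfg["lipid_genes"], outdir / "select",
    )
    manifest["stages"]["select"] = sel
    gwas = stage_gwas(sim["genotypes"], sim["phenotypes"], cfg, outdir / "gwas")
    manifest["stages"]["gwas"] = gwas
    # manifest paths are stored relative to the output directory so that a
    # run is relocatable and reruns are byte-identical
    portable = _relativize(manifest, str(outdir))
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(portable, fh, indent=2, sort_keys=True)
    return manifest


def _relativize(obj, base: str):
    sep_base = base.rstrip("/") + "/"
    if isinstance(obj, dict):
        return {k: _relativize(v, base) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_relativize(v, base) for v in obj]
    if isinstance(obj, str) and obj.startswith(sep_base):
        return obj[len(sep_base):]
    return obj


def report(manifest: dict) -> str:
    """Human-readable summary of a run manifest."""
    lines = ["indelgwas run report", "=" * 40]
    lines.append(f"config hash : {manifest.get('config_hash', '?')}")
    lines.append(f"seed        : {manifest.get('seed', '?')}")
    stages = manifest.get("stages", {})
    acc = stages.get("consensus", {}).get("accounting")
    if acc:
        lines.append("")
        lines.append("filter ledger")
        lines.append(f"  per caller     : {acc['n_per_caller']}")
        lines.append(f"  common         : {acc['n_common']}")
        lines.append(f"  discordant     : {acc['n_discordant']}")
        lines.append(f"  multi-allelic  : {acc['n_multiallelic_inconsistent']}")
        lines.append(f"  fixed-alt      : {acc['n_fixed_alt']}")
        lines.append(f"  final          : {acc['n_final']}")
        implied = cns.ledger_check(
            acc["n_common"], acc["n_discordant"],
            acc["n_multiallelic_inconsistent"], acc["n_fixed_alt"],
        )
        lines.append(f"  conservation   : {'OK' if implied == acc['n_final'] else 'BROKEN'}")
    else:
        lines.append("consensus stage missing (partial report)")
    sel = stages.get("select", {})
    if sel:
        lines.append("")
        lines.append(f"candidates selected : {sel.get('n_candidates', 0)}")
    gwas = stages.get("gwas", {})
    for label, s in gwas.get("scans", {}).items():
        lines.append(
            f"scan {label:10s}: {s['n_markers']} markers, "
            f"{s['n_significant']} significant, {s['n_suggestive']} suggestive"
        )
    return "\n".join(lines)
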