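"""Random genome and gene-model construction.

Genes are built inside-out: a spliced transcript (5' UTR + CDS + 3' UTR) is
generated first -- the CDS starts with ATG, ends with a stop codon, contains
no internal stop and has length divisible by 3 -- then written across 2+
exons separated by introns, reverse-complemented for minus-strand genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from Bio.Seq import Seq

from ..consequence import GeneModel, Transcript

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]

MIN_INTRON = 30
MAX_INTRON = 200
MIN_EXON_PART = 30


@dataclass
class SimulatedGenome:
    chromosomes: dict  # name -> sequence string (A/C/G/T)
    gene_models: list = field(default_factory=list)  # list[GeneModel]

    def __getitem__(self, chrom: str) -> str:
        return self.chromosomes[chrom]

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.chromosomes.values())

    def lengths(self) -> dict:
        return {c: len(s) for c, s in self.chromosomes.items()}


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    body = "".join(_CODONS[i] for i in rng.integers(0, len(_CODONS), size=n_codons - 2))
    stop = ("TAA", "TAG", "TGA")[rng.integers(0, 3)]
    return "ATG" + body + stop


def _build_gene(
    rng: np.random.Generator,
    gene_id: str,
    chrom: str,
    region_start: int,
    region_len: int,
) -> tuple:
    """Return (GeneModel, genomic_subsequence) occupying at most region_len bases."""
    strand = "+" if rng.random() < 0.5 else "-"
    n_exons = int(rng.integers(2, 5))
    n_codons = int(rng.integers(80, 200))
    utr5 = int(rng.integers(30, 90))
    utr3 = int(rng.integers(30, 90))
    cds = _random_cds(rng, n_codons)
    transcript = _random_seq(rng, utr5) + cds + _random_seq(rng, utr3)

    exonic = len(transcript)
    # split the exonic sequence into n_exons contiguous parts of >= MIN_EXON_PART
    while True:
        cuts = np.sort(rng.integers(MIN_EXON_PART, exonic - MIN_EXON_PART, size=n_exons - 1))
        sizes = np.diff(np.concatenate(([0], cuts, [exonic])))
        if (sizes >= MIN_EXON_PART).all():
            break
    introns = rng.integers(MIN_INTRON, MAX_INTRON + 1, size=n_exons - 1)
    span = exonic + int(introns.sum())
    if span > region_len:
        raise ValueError(
            f"gene {gene_id} (span {span}) does not fit in region of {region_len} bp"
        )
    start = region_start + int(rng.integers(0, region_len - span + 1))

    # genomic exon sequence in genome order
    genomic_tx = transcript if strand == "+" else str(Seq(transcript).reverse_complement())
    exon_sizes = sizes if strand == "+" else sizes[::-1]

    exons = []
    pieces = []
    g = start
    off = 0
    for i, sz in enumerate(exon_sizes):
        exons.append((g, g + int(sz) - 1))
        pieces.append(genomic_tx[off : off + int(sz)])
        off += int(sz)
        g += int(sz)
        if i < n_exons - 1:
            ilen = int(introns[i])
            pieces.append(_random_seq(rng, ilen))
            g += ilen
    subseq = "".join(pieces)

    # CDS genomic intervals: transcript offsets [utr5, utr5+len(cds)) mapped back
    tx_cds_lo, tx_cds_hi = utr5, utr5 + len(cds) - 1  # transcript coords, inclusive
    cds_intervals = []
    off = 0
    for i, (es, ee) in enumerate(exons):
        sz = ee - es + 1
        # transcript offsets covered by this exon
        if strand == "+":
            t0, t1 = off, off + sz - 1
        else:
            t1 = exonic - 1 - off
            t0 = t1 - sz + 1
        lo = max(t0, tx_cds_lo)
        hi = min(t1, tx_cds_hi)
        if lo <= hi:
            if strand == "+":
                cds_intervals.append((es + (lo - t0), es + (hi - t0)))
            else:
                cds_intervals.append((es + (t1 - hi), es + (t1 - lo)))
        off += sz
    tx = Transcript(
        transcript_id=gene_id + ".t1",
        exons=exons,
        cds=sorted(cds_intervals),
        biotype="protein_coding",
    )
    gene = GeneModel(gene_id=gene_id, chrom=chrom, strand=strand, transcripts=[tx])
    return gene, start, subseq


def generate_genome(
    n_chromosomes: int,
    chrom_length: int,
    n_genes: int,
    seed: int,
    fasta_path: Optional[str] = None,
    gff3_path: Optional[str] = None,
) -> SimulatedGenome:
    """Generate a random genome with non-overlapping multi-exon genes.

    Deterministic for a fixed seed.  Raises ``ValueError`` when the requested
    genes cannot be packed into the chromosomes.
    """
    if chrom_length < 10_000:
        raise ValueError("chromosome length must be >= 10 kb")
    rng = np.random.default_rng(seed)
    names = [f"chr{i + 1}" for i in range(n_chromosomes)]
    chrom_seqs = {name: list(_random_seq(rng, chrom_length)) for name in names}

    genes: list = []
    per_chrom = [n_genes // n_chromosomes + (1 if i < n_genes % n_chromosomes else 0)
                 for i in range(n_chromosomes)]
    margin = 500
    for name, k in zip(names, per_chrom):
        if k == 0:
            continue
        slot = (chrom_length - 2 * margin) // k
        if slot < 1500:
            raise ValueError(
                f"cannot pack {k} genes into {name} of {chrom_length} bp"
            )
        for j in range(k):
            region_start = margin + j * slot + 1  # 1-based
            gene, start, subseq = _build_gene(
                rng, f"gene{len(genes) + 1}", name, region_start, slot - 200
            )
            s = chrom_seqs[name]
            s[start - 1 : start - 1 + len(subseq)] = list(subseq)
            genes.append(gene)

    genome = SimulatedGenome(
        chromosomes={n: "".join(s) for n, s in chrom_seqs.items()},
        gene_models=genes,
    )
    if fasta_path:
        write_fasta(genome, fasta_path)
    if gff3_path:
        write_gff3(genome.gene_models, gff3_path)
    return genome


def write_fasta(genome: SimulatedGenome, path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.chromosomes.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_gff3(genes, path) -> None:
    """Write gene models as GFF3 (1-based inclusive coordinates)."""
    lines = ["##gff-version 3"]
    for gene in genes:
        gs = min(t.start for t in gene.transcripts)
        ge = max(t.end for t in gene.transcripts)
        lines.append(
            "\t".join(
                [gene.chrom, "indelgwas", "gene", str(gs), str(ge), ".", gene.strand,
                 ".", f"ID={gene.gene_id};biotype={gene.biotype}"]
            )
        )
        for tx in gene.transcripts:
            lines.append(
                "\t".join(
                    [gene.chrom, "indelgwas", "mRNA", str(tx.start), str(tx.end), ".",
                     gene.strand, ".",
                     f"ID={tx.transcript_id};Parent={gene.gene_id};biotype={tx.biotype}"]
                )
            )
            for i, (s, e) in enumerate(tx.exons, 1):
                lines.append(
                    "\t".join(
                        [gene.chrom, "indelgwas", "exon", str(s), str(e), ".",
                         gene.strand, ".",
                         f"ID={tx.transcript_id}.exon{i};Parent={tx.transcript_id}"]
                    )
                )
            # CDS phases follow coding order (5'->3' on the strand)
            coding = tx.cds if gene.strand == "+" else tx.cds[::-1]
            acc = 0
            phased = []
            for s, e in coding:
                phase = (3 - acc % 3) % 3
                phased.append((s, e, phase))
                acc += e - s + 1
            for s, e, phase in sorted(phased):
                lines.append(
                    "\t".join(
                        [gene.chrom, "indelgwas", "CDS", str(s), str(e), ".",
                         gene.strand, str(phase),
                         f"ID={tx.transcript_id}.cds;Parent={tx.transcript_id}"]
                    )
                )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path) -> list:
    """Read gene models written by :func:`write_gff3` back into GeneModel objects."""
    genes: dict = {}
    tx_meta: dict = {}
    exons: dict = {}
    cds: dict = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            chrom, _, ftype, start, end, _, strand, _, attrs = line.rstrip("\n").split("\t")
            a = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            if ftype == "gene":
                genes[a["ID"]] = {
                    "chrom": chrom, "strand": strand,
                    "biotype": a.get("biotype", "coding"), "transcripts": [],
                }
            elif ftype in {"mRNA", "transcript"}:
                tx_meta[a["ID"]] = {
                    "parent": a["Parent"], "biotype": a.get("biotype", "protein_coding")
                }
                genes[a["Parent"]]["transcripts"].append(a["ID"])
            elif ftype == "exon":
                exons.setdefault(a["Parent"], []).append((int(start), int(end)))
            elif ftype == "CDS":
                cds.setdefault(a["Parent"], []).append((int(start), int(end)))
    out = []
    for gid, g in genes.items():
        txs = [
            Transcript(
                transcript_id=tid,
                exons=exons.get(tid, []),
                cds=cds.get(tid, []),
                biotype=tx_meta[tid]["biotype"],
            )
            for tid in g["transcripts"]
        ]
        out.append(
            GeneModel(gene_id=gid, chrom=g["chrom"], strand=g["strand"],
                      transcripts=txs, biotype=g["biotype"])
        )
    return out
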