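"""Truth-variant planting: indels and SNPs at breed-stratified frequencies."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from ..vario import NormalizedKey, normalize
from ..consequence import GeneModel
from .genome import SimulatedGenome

MAX_DEL_LEN = 54
MAX_INS_LEN = 32
DEFAULT_DELETION_FRACTION = 0.529

_BASES = "ACGT"


@dataclass
class TruthVariant:
    key: NormalizedKey
    variant_class: str  # "insertion" | "deletion" | "snp"
    true_freq_IB: float
    true_freq_LD: float
    planted_effect: float = 0.0

    def __post_init__(self) -> None:
        for f in (self.true_freq_IB, self.true_freq_LD):
            if not 0.0 <= f <= 1.0:
                raise ValueError("frequencies must lie in [0, 1]")
        if self.variant_class in ("insertion", "deletion") and self.key.indel_length < 1:
            raise ValueError("indel must change length by >= 1")


def _draw_length(rng: np.random.Generator, mean_len: float, cap: int) -> int:
    p = min(1.0, 1.0 / mean_len)
    while True:
        n = int(rng.geometric(p))
        if n <= cap:
            return n


def _make_indel(
    rng: np.random.Generator,
    genome: SimulatedGenome,
    chrom: str,
    pos: int,
    deletion_fraction: float,
    mean_len: float,
) -> Optional[NormalizedKey]:
    seq = genome.chromosomes[chrom]
    if rng.random() < deletion_fraction:
        length = _draw_length(rng, mean_len, MAX_DEL_LEN)
        if pos + length >= len(seq):
            return None
        ref = seq[pos - 1 : pos + length]
        alt = seq[pos - 1]
    else:
        length = _draw_length(rng, mean_len, MAX_INS_LEN)
        ref = seq[pos - 1]
        ins = "".join(_BASES[i] for i in rng.integers(0, 4, size=length))
        alt = ref + ins
    try:
        return normalize((chrom, pos, ref, alt), genome)
    except Exception:
        return None


def _make_snp(
    rng: np.random.Generator, genome: SimulatedGenome, chrom: str, pos: int
) -> NormalizedKey:
    ref = genome.chromosomes[chrom][pos - 1]
    alts = [b for b in _BASES if b != ref]
    return NormalizedKey(chrom, pos, ref, alts[rng.integers(0, 3)])


def plant_truth_variants(
    genome: SimulatedGenome,
    n_indels: int,
    n_snps: int,
    freq_spec: Sequence,
    seed: int,
    deletion_fraction: float = DEFAULT_DELETION_FRACTION,
    mean_indel_len: float = 2.0,
    min_spacing: int = 80,
    max_retries: int = 200,
) -> list:
    """Plant ``n_indels`` indels and ``n_snps`` SNPs with left-aligned keys.

    Each variant is assigned a ``(freq_IB, freq_LD)`` stratum from
    ``freq_spec``, cycling so that every stratum receives at least one variant
    (when enough variants are requested).  Indel lengths follow a geometric
    distribution (mode 1 bp), capped at 54 bp for deletions and 32 bp for
    insertions; site collisions are resolved by resampling.
    """
    if not freq_spec:
        raise ValueError("freq_spec must contain at least one stratum")
    for f_ib, f_ld in freq_spec:
        if not (0.0 <= f_ib <= 1.0 and 0.0 <= f_ld <= 1.0):
            raise ValueError("stratum frequencies must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    chroms = list(genome.chromosomes)
    lengths = genome.lengths()
    # spacing check via bins of width min_spacing: only neighbours can clash
    occupied: dict = {c: {} for c in chroms}  # chrom -> {bin: [positions]}
    variants: list = []

    def _free(chrom: str, pos: int) -> bool:
        bins = occupied[chrom]
        b = pos // min_spacing
        for bb in (b - 1, b, b + 1):
            for q in bins.get(bb, ()):
                if abs(pos - q) < min_spacing:
                    return False
        return True

    def _occupy(chrom: str, pos: int) -> None:
        occupied[chrom].setdefault(pos // min_spacing, []).append(pos)

    total = n_indels + n_snps
    kinds = ["indel"] * n_indels + ["snp"] * n_snps
    for i, kind in enumerate(kinds):
        stratum = freq_spec[i % len(freq_spec)]
        key = None
        for _ in range(max_retries):
            chrom = chroms[rng.integers(0, len(chroms))]
            pos = int(rng.integers(MAX_DEL_LEN + 2, lengths[chrom] - MAX_DEL_LEN - 2))
            if not _free(chrom, pos):
                continue
            if kind == "indel":
                key = _make_indel(rng, genome, chrom, pos, deletion_fraction, mean_indel_len)
            else:
                key = _make_snp(rng, genome, chrom, pos)
            if key is not None and _free(key.chrom, key.pos):
                break
            key = None
        if key is None:
            raise RuntimeError(
                f"could not place variant {i + 1}/{total} after {max_retries} retries"
            )
        _occupy(key.chrom, key.pos)
        if kind == "indel":
            vclass = "deletion" if len(key.ref) > len(key.alt) else "insertion"
        else:
            vclass = "snp"
        variants.append(
            TruthVariant(
                key=key,
                variant_class=vclass,
                true_freq_IB=float(stratum[0]),
                true_freq_LD=float(stratum[1]),
            )
        )
    variants.sort(key=lambda v: (v.key.chrom, v.key.pos))
    return variants


def plant_coding_indel(
    genome: SimulatedGenome,
    gene: GeneModel,
    freq_IB: float = 1.0,
    freq_LD: float = 0.0,
    planted_effect: float = 0.0,
    n_codons: int = 1,
    seed: int = 0,
) -> TruthVariant:
    """Plant a codon-aligned inframe deletion inside a gene's CDS.

    Picks an interior codon of the largest CDS interval, away from splice
    regions and the start/stop codons, so the annotation is a plain
    ``inframe_deletion`` (Moderate).
    """
    rng = np.random.default_rng(seed)
    tx = gene.transcripts[0]
    cds_len = tx.cds_len
    length = 3 * n_codons
    # codon index range well inside the CDS
    lo_codon, hi_codon = 4, cds_len // 3 - 4 - n_codons
    if hi_codon <= lo_codon:
        raise ValueError("CDS too short for an interior codon deletion")
    for _ in range(200):
        codon = int(rng.integers(lo_codon, hi_codon))
        t0 = codon * 3  # transcript-strand CDS offset of first deleted base
        # map to plus-strand CDS offset
        if gene.strand == "+":
            p0 = t0
        else:
            p0 = cds_len - (t0 + length)
        # walk CDS intervals to find the genomic position
        off = 0
        gstart = None
        for s, e in tx.cds:
            sz = e - s + 1
            if off <= p0 < off + sz:
                gstart = s + (p0 - off)
                within = gstart + length - 1 <= e
                break
            off += sz
        if gstart is None or not within:
            continue
        chrom_seq = genome.chromosomes[gene.chrom]
        pos = gstart - 1  # VCF anchor base before the deleted run
        if pos < 1:
            continue
        ref = chrom_seq[pos - 1 : pos + length]
        alt = chrom_seq[pos - 1]
        key = normalize((gene.chrom, pos, ref, alt), genome)
        return TruthVariant(
            key=key,
            variant_class="deletion",
            true_freq_IB=freq_IB,
            true_freq_LD=freq_LD,
            planted_effect=planted_effect,
        )
    raise RuntimeError(f"could not place a coding deletion in {gene.gene_id}")
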