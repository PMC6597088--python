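"""Emulated caller call-sets: dropout, genotype error, representation jitter
and unlinked false positives applied independently per caller."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..vario import NormalizedKey, VariantRecord, fetch_seq, normalize
from .founders import FounderSet
from .genome import SimulatedGenome

_BASES = "ACGT"


@dataclass
class CallerProfile:
    name: str
    sensitivity: float = 1.0
    genotype_error_rate: float = 0.0
    representation_jitter_rate: float = 0.0
    false_positive_rate_per_mb: float = 0.0

    def __post_init__(self) -> None:
        for r in (self.sensitivity, self.genotype_error_rate, self.representation_jitter_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"rate out of [0, 1] in profile {self.name!r}")
        if self.false_positive_rate_per_mb < 0:
            raise ValueError("false-positive rate must be >= 0")


def _window_mutated(genome, chrom, pos, ref, alt, wstart, wend) -> str:
    w = fetch_seq(genome, chrom, wstart, wend)
    off = pos - wstart
    if w[off : off + len(ref)] != ref:
        raise AssertionError("ref mismatch while validating representation")
    return w[:off] + alt + w[off + len(ref) :]


def alternative_representation(
    key: NormalizedKey, genome, rng: np.random.Generator, max_shift: int = 6
):
    """An equivalent but non-left-aligned representation of an indel.

    Tries right-shifted representations (valid in repeat context), validated
    by comparing mutated windows; falls back to padding both alleles with the
    next reference base, which is always equivalent.
    """
    chrom, pos, ref, alt = key.chrom, key.pos, key.ref, key.alt
    wstart = max(1, pos - 1)
    wend = pos + len(ref) + max_shift + len(alt) + 2
    chrom_len = len(
        genome.chromosomes[chrom] if hasattr(genome, "chromosomes") else genome[chrom]
    )
    wend = min(wend, chrom_len)
    truth_m = _window_mutated(genome, chrom, pos, ref, alt, wstart, wend)

    candidates = []
    is_del = len(ref) > len(alt)
    for t in range(1, max_shift + 1):
        p = pos + t
        if is_del:
            if p + len(ref) - 1 > wend:
                break
            cref = fetch_seq(genome, chrom, p, p + len(ref) - 1)
            calt = fetch_seq(genome, chrom, p, p)
        else:
            if p > wend:
                break
            cref = fetch_seq(genome, chrom, p, p)
            # inserted run must rotate through matching reference bases
            ins = alt[1:]
            shift_ok = fetch_seq(genome, chrom, pos + 1, p) == (ins * ((t // len(ins)) + 1))[:t]
            if not shift_ok:
                break
            rot = t % len(ins)
            calt = cref + ins[rot:] + ins[:rot]
        try:
            if _window_mutated(genome, chrom, p, cref, calt, wstart, wend) == truth_m:
                candidates.append((p, cref, calt))
        except AssertionError:
            break
    if candidates:
        p, cref, calt = candidates[int(rng.integers(0, len(candidates)))]
        return p, cref, calt
    # pad with the next reference base
    nxt = pos + len(ref)
    if nxt <= chrom_len:
        b = fetch_seq(genome, chrom, nxt, nxt)
        return pos, ref + b, alt + b
    return pos, ref, alt


def simulate_callsets(
    founders: FounderSet,
    genome: SimulatedGenome,
    profiles,
    seed: int,
) -> dict:
    """Emulate k >= 2 callers over the founder truth set.

    Returns ``{caller_name: list[VariantRecord]}``.  Each caller independently
    drops variants (1 - sensitivity), perturbs genotypes, re-expresses a
    jitter fraction of indels in an equivalent non-left-aligned representation
    and plants unlinked false positives at truth-free sites.
    """
    profiles = list(profiles)
    if len(profiles) < 2:
        raise ValueError("need at least two caller profiles")
    rng = np.random.default_rng(seed)
    sample_names = tuple(founders.names)
    genotypes = founders.genotypes  # dosage 0/1/2
    truth_keys = {(v.key.chrom, v.key.pos) for v in founders.variants}
    lengths = genome.lengths()
    chroms = list(lengths)
    total_mb = genome.total_length / 1e6

    callsets: dict = {}
    for prof in profiles:
        crng = np.random.default_rng(rng.integers(0, 2**63))
        records = []
        for i, v in enumerate(founders.variants):
            if crng.random() > prof.sensitivity:
                continue
            gts = list(genotypes[i])
            for s in range(len(gts)):
                if crng.random() < prof.genotype_error_rate:
                    gts[s] = int(crng.choice([g for g in (0, 1, 2) if g != gts[s]]))
            chrom, pos, ref, alt = v.key.chrom, v.key.pos, v.key.ref, v.key.alt
            if v.key.is_indel and crng.random() < prof.representation_jitter_rate:
                pos, ref, alt = alternative_representation(v.key, genome, crng)
            records.append(
                VariantRecord(
                    chrom=chrom, pos=pos, ref=ref, alt=alt,
                    genotypes=[int(g) for g in gts],
                    caller=prof.name, sample_names=sample_names,
                )
            )
        # false positives at sites absent from truth
        n_fp = int(crng.poisson(prof.false_positive_rate_per_mb * total_mb))
        placed = 0
        guard = 0
        while placed < n_fp and guard < 50 * (n_fp + 1):
            guard += 1
            chrom = chroms[crng.integers(0, len(chroms))]
            pos = int(crng.integers(60, lengths[chrom] - 60))
            length = int(crng.geometric(0.5))
            if length > 10:
                continue
            seq = genome.chromosomes[chrom]
            if crng.random() < 0.5:
                ref = seq[pos - 1 : pos + length]
                alt = seq[pos - 1]
            else:
                ref = seq[pos - 1]
                alt = ref + "".join(_BASES[b] for b in crng.integers(0, 4, size=length))
            try:
                k = normalize((chrom, pos, ref, alt), genome)
            except Exception:
                continue
            if (k.chrom, k.pos) in truth_keys:
                continue
            gts = [int(g) for g in crng.integers(0, 3, size=len(sample_names))]
            if not any(gts):
                gts[int(crng.integers(0, len(gts)))] = 1
            records.append(
                VariantRecord(
                    chrom=k.chrom, pos=k.pos, ref=k.ref, alt=k.alt, genotypes=gts,
                    caller=prof.name, sample_names=sample_names,
                )
            )
            truth_keys.add((k.chrom, k.pos))  # keep FP sites disjoint across callers too
            placed += 1
        records.sort(key=lambda r: (r.chrom, r.pos, r.ref, r.alt))
        callsets[prof.name] = records
    return callsets
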