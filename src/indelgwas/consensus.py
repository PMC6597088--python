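"""Multi-caller indel consensus with explicit filter accounting.

The cascade is fixed: (1) keep only indels found by *all* callers after
normalization; (2) resolve per-sample genotypes by 2-of-k majority,
discarding the whole variant when any sample is fully discordant; (3) discard
positions carrying more than one distinct alt allele; (4) discard variants
homozygous-alt in every sample.  Every variant entering the common set is
assigned exactly one fate, so the accounting identity

    n_common == n_final + n_discordant + n_multiallelic + n_fixed_alt

holds on every input.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Optional

from .vario import NormalizedKey, VariantRecord, normalize, variant_class

log = logging.getLogger(__name__)

RETAINED = "retained"
DISCORDANT = "discarded_genotype_discordant"
MULTIALLELIC = "discarded_multiallelic_inconsistent"
FIXED_ALT = "discarded_fixed_alt"
NOT_IN_ALL = "not_in_all_callers"


@dataclass
class ConsensusVariant:
    key: NormalizedKey
    genotypes: list                 # resolved per-sample genotypes (dosage or None)
    support: set                    # caller labels
    fate: str = RETAINED


@dataclass
class FilterAccounting:
    n_union: int = 0
    n_per_caller: dict = field(default_factory=dict)
    n_common: int = 0
    n_discordant: int = 0
    n_multiallelic_inconsistent: int = 0
    n_fixed_alt: int = 0
    n_final: int = 0

    def check(self) -> None:
        lhs = self.n_common
        rhs = (
            self.n_final
            + self.n_discordant
            + self.n_multiallelic_inconsistent
            + self.n_fixed_alt
        )
        if lhs != rhs:
            raise AssertionError(
                f"filter ledger broken: {lhs} common != {rhs} accounted"
            )

    def as_dict(self) -> dict:
        return {
            "n_union": self.n_union,
            "n_per_caller": dict(self.n_per_caller),
            "n_common": self.n_common,
            "n_discordant": self.n_discordant,
            "n_multiallelic_inconsistent": self.n_multiallelic_inconsistent,
            "n_fixed_alt": self.n_fixed_alt,
            "n_final": self.n_final,
        }


def ledger_check(n_common: int, n_discordant: int, n_multiallelic: int, n_fixed: int) -> int:
    """Bookkeeping helper: final count implied by the discard classes."""
    return n_common - n_discordant - n_multiallelic - n_fixed


def intersect(callsets: dict, genome, indels_only: bool = True):
    """Group caller records by normalized key.

    ``callsets`` maps caller label -> iterable of VariantRecord.  Returns
    ``(groups, venn)`` where ``groups`` maps key -> {caller: record} over keys
    present in *all* callers and ``venn`` reports per-caller, pairwise and
    k-way overlap counts plus the union.  Duplicate keys within one call-set
    keep the first record (logged).
    """
    per_caller: dict = {}
    for caller, records in callsets.items():
        seen: dict = {}
        dups = 0
        for rec in records:
            if indels_only and not rec.is_indel:
                continue
            key = normalize(rec, genome)
            if key in seen:
                dups += 1
                continue
            seen[key] = rec
        if dups:
            log.info("intersect: %d duplicate keys in call-set %s (kept first)", dups, caller)
        per_caller[caller] = seen

    callers = list(per_caller)
    keysets = {c: set(per_caller[c]) for c in callers}
    union = set().union(*keysets.values()) if keysets else set()
    common = set.intersection(*keysets.values()) if keysets else set()
    venn = {
        "per_caller": {c: len(keysets[c]) for c in callers},
        "pairwise": {
            f"{a}&{b}": len(keysets[a] & keysets[b]) for a, b in combinations(callers, 2)
        },
        "common": len(common),
        "union": len(union),
    }
    groups = {
        key: {c: per_caller[c][key] for c in callers} for key in sorted(
            common, key=lambda k: (k.chrom, k.pos, k.ref, k.alt)
        )
    }
    return groups, venn


def resolve_genotypes(key: NormalizedKey, group: dict) -> ConsensusVariant:
    """Majority (2-of-k) per-sample genotype resolution.

    A sample's genotype is the majority value over callers with a non-missing
    call; missing calls do not vote.  Any sample whose non-missing calls have
    no majority makes the whole variant discordant, as does a variant with
    every sample missing everywhere.
    """
    records = list(group.values())
    n_samples = len(records[0].genotypes)
    resolved: list = []
    fate = RETAINED
    for s in range(n_samples):
        votes = [r.genotypes[s] for r in records if r.genotypes[s] is not None]
        if not votes:
            resolved.append(None)
            continue
        (top, top_n), *rest = Counter(votes).most_common()
        if len(votes) == 1 or top_n > max((n for _, n in rest), default=0):
            resolved.append(top)
        else:
            fate = DISCORDANT
            resolved.append(None)
    if all(g is None for g in resolved):
        fate = DISCORDANT
    return ConsensusVariant(
        key=key, genotypes=resolved, support=set(group), fate=fate
    )


def filter_alleles(variants: Iterable[ConsensusVariant]) -> list:
    """Discard every variant at a position carrying >1 distinct alt allele."""
    variants = list(variants)
    by_pos = defaultdict(list)
    for v in variants:
        by_pos[(v.key.chrom, v.key.pos)].append(v)
    for _, group in by_pos.items():
        live = [v for v in group if v.fate == RETAINED]
        alts = {(v.key.ref, v.key.alt) for v in live}
        if len(alts) > 1:
            for v in live:
                v.fate = MULTIALLELIC
    return variants


def filter_fixed_alt(
    variants: Iterable[ConsensusVariant], require_complete: bool = True
) -> list:
    """Discard variants hom-alt in all samples (non-segregating).

    With ``require_complete`` (default) a variant with any missing genotype is
    kept; otherwise all *non-missing* genotypes hom-alt (and at least one
    non-missing) suffices to discard.
    """
    variants = list(variants)
    for v in variants:
        if v.fate != RETAINED:
            continue
        non_missing = [g for g in v.genotypes if g is not None]
        if not non_missing:
            continue
        all_hom_alt = all(g == 2 for g in non_missing)
        complete = len(non_missing) == len(v.genotypes)
        if all_hom_alt and (complete or not require_complete):
            v.fate = FIXED_ALT
    return variants


def accounting(variants: Iterable[ConsensusVariant], venn: Optional[dict] = None) -> FilterAccounting:
    counts = Counter(v.fate for v in variants)
    unknown = set(counts) - {RETAINED, DISCORDANT, MULTIALLELIC, FIXED_ALT}
    if unknown:
        raise ValueError(f"variants with unassigned fate: {unknown}")
    acc = FilterAccounting(
        n_union=(venn or {}).get("union", 0),
        n_per_caller=(venn or {}).get("per_caller", {}),
        n_common=sum(counts.values()),
        n_discordant=counts.get(DISCORDANT, 0),
        n_multiallelic_inconsistent=counts.get(MULTIALLELIC, 0),
        n_fixed_alt=counts.get(FIXED_ALT, 0),
        n_final=counts.get(RETAINED, 0),
    )
    acc.check()
    return acc


def run_consensus(
    callsets: dict, genome, require_complete_fixed_alt: bool = True
):
    """Full cascade; returns ``(variants, accounting)``.

    Filter order: common -> genotype concordance -> multi-alt positions ->
    fixed-alt, with each variant keeping the fate of the first stage that
    discarded it.
    """
    groups, venn = intersect(callsets, genome)
    variants = [resolve_genotypes(key, group) for key, group in groups.items()]
    log.info("consensus: %d common, %d discordant", len(variants),
             sum(v.fate == DISCORDANT for v in variants))
    variants = filter_alleles(variants)
    variants = filter_fixed_alt(variants, require_complete=require_complete_fixed_alt)
    acc = accounting(variants, venn)
    log.info(
        "consensus ledger: common=%d discordant=%d multiallelic=%d fixed_alt=%d final=%d",
        acc.n_common, acc.n_discordant, acc.n_multiallelic_inconsistent,
        acc.n_fixed_alt, acc.n_final,
    )
    return variants, acc


def retained(variants: Iterable[ConsensusVariant]) -> list:
    return [v for v in variants if v.fate == RETAINED]


def chromosome_density(variants: Iterable[ConsensusVariant], genome) -> list:
    """Indels per Mb for every chromosome, sorted ascending by density."""
    if hasattr(genome, "lengths"):
        lengths = genome.lengths()
    else:  # mapping of name -> sequence or name -> length
        lengths = {
            c: (v if isinstance(v, int) else len(v)) for c, v in genome.items()
        }
    counts = Counter(v.key.chrom for v in retained(variants))
    out = []
    for chrom, length in lengths.items():
        if length <= 0:
            raise ValueError(f"zero-length chromosome {chrom!r}")
        out.append((chrom, counts.get(chrom, 0) / (length / 1e6)))
    out.sort(key=lambda t: (t[1], t[0]))
    return out


def length_spectrum(variants: Iterable[ConsensusVariant]):
    """Histogram of (class, length) plus the deletion fraction.

    Returns ``(histogram, deletion_fraction)``; the fraction is None for an
    empty retained set.
    """
    hist: Counter = Counter()
    n_del = n_tot = 0
    for v in retained(variants):
        cls = variant_class(v.key)
        hist[(cls, v.key.indel_length)] += 1
        n_tot += 1
        n_del += cls == "deletion"
    return dict(hist), (n_del / n_tot if n_tot else None)
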