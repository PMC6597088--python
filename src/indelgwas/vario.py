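"""Variant records, VCF I/O and the canonical (left-aligned, minimal) indel key.

Every other module compares indels through :class:`NormalizedKey`, so the
normalization algorithm here is the single place where alternative
representations of the same edit are unified.

Coordinates are 1-based throughout; ``pos`` is the anchor base preceding the
inserted/deleted sequence, as in VCF.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import pysam

log = logging.getLogger(__name__)

#: per-sample genotype encoding: number of copies of the alt allele
#: (0 = hom-ref, 1 = het, 2 = hom-alt, None = missing)
Genotype = Optional[int]

HOM_REF, HET, HOM_ALT = 0, 1, 2

_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", None: "./."}


class VcfError(ValueError):
    """Malformed VCF content (bad header or GT field)."""


class NormalizationError(ValueError):
    """Reference allele does not match the genome, or no left context exists."""


def fetch_seq(genome, chrom: str, start: int, end: int) -> str:
    """Return genome bases ``start..end`` (1-based, inclusive) as an upper-case string.

    ``genome`` may be a mapping of chromosome name -> sequence string, an
    object with a ``chromosomes`` mapping attribute, or a ``pyfaidx.Fasta``.
    """
    if hasattr(genome, "chromosomes"):
        genome = genome.chromosomes
    try:
        seq = genome[chrom]
    except KeyError as exc:
        raise NormalizationError(f"unknown chromosome {chrom!r}") from exc
    if end < start:
        return ""
    return str(seq[start - 1 : end]).upper()


@dataclass(frozen=True)
class NormalizedKey:
    """Left-aligned minimal representation of a variant.

    ``ref`` and ``alt`` share exactly one leading anchor base (for indels) and
    no trailing bases; normalizing a NormalizedKey is the identity.
    """

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")
        if self.pos < 1:
            raise ValueError("pos must be >= 1")

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)

    @property
    def indel_length(self) -> int:
        return abs(len(self.ref) - len(self.alt))

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


@dataclass
class VariantRecord:
    """One caller's call at one site, with per-sample genotypes."""

    chrom: str
    pos: int
    ref: str
    alt: str
    genotypes: list  # list[Genotype], ordered as sample_names
    caller: str = ""
    sample_names: Sequence[str] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"ref == alt at {self.chrom}:{self.pos}")
        if self.pos < 1:
            raise ValueError("pos must be >= 1")
        if self.sample_names and len(self.genotypes) != len(self.sample_names):
            raise ValueError("genotype list length must equal sample count")

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)


def normalize(v, genome) -> NormalizedKey:
    """Left-align and minimalize a variant against the genome.

    Accepts a :class:`VariantRecord`, :class:`NormalizedKey` or a
    ``(chrom, pos, ref, alt)`` tuple.  Algorithm: repeatedly trim a shared
    trailing base, extending both alleles with the genome base to the left
    whenever an allele would become empty; finally trim shared leading bases
    while both alleles keep length >= 2.  The result is the unique leftmost
    minimal representation.
    """
    if isinstance(v, (VariantRecord, NormalizedKey)):
        chrom, pos, ref, alt = v.chrom, v.pos, v.ref, v.alt
    else:
        chrom, pos, ref, alt = v
    ref = ref.upper()
    alt = alt.upper()
    if ref == alt:
        raise NormalizationError(f"ref == alt at {chrom}:{pos}")
    observed = fetch_seq(genome, chrom, pos, pos + len(ref) - 1)
    if observed != ref:
        raise NormalizationError(
            f"ref allele {ref!r} does not match genome ({observed!r}) at {chrom}:{pos}"
        )
    while True:
        if ref and alt and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
        if not ref or not alt:
            if pos <= 1:
                raise NormalizationError(
                    f"cannot left-extend past start of {chrom} while normalizing"
                )
            pos -= 1
            b = fetch_seq(genome, chrom, pos, pos)
            ref, alt = b + ref, b + alt
        if ref and alt and ref[-1] != alt[-1]:
            break
    while len(ref) >= 2 and len(alt) >= 2 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return NormalizedKey(chrom, pos, ref, alt)


def variant_class(k: NormalizedKey) -> str:
    """Classify an indel key as ``"insertion"`` or ``"deletion"``.

    Raises ``ValueError`` for non-indels (SNPs/MNPs).
    """
    if len(k.ref) == len(k.alt):
        raise ValueError(f"{k} is not an indel")
    return "deletion" if len(k.ref) > len(k.alt) else "insertion"


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------


class VcfReadResult:
    """Records read from a VCF plus skip accounting; iterates over records."""

    def __init__(self, records: list, samples: Sequence[str], n_skipped: int):
        self.records = records
        self.samples = list(samples)
        self.n_skipped = n_skipped

    def __iter__(self) -> Iterator[VariantRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, i):
        return self.records[i]


def _is_symbolic(alt: str) -> bool:
    return alt.startswith("<") or "[" in alt or "]" in alt or alt in {"*", "."}


def read_vcf(path, caller: str = "", strict: bool = False) -> VcfReadResult:
    """Read a (possibly multi-sample) VCF into biallelic :class:`VariantRecord` s.

    Multi-allelic lines are split into one record per alt allele; symbolic
    alleles and breakends are skipped (counted) unless ``strict`` is set, in
    which case they raise :class:`VcfError`.
    """
    path = str(path)
    records: list[VariantRecord] = []
    n_skipped = 0
    try:
        vf = pysam.VariantFile(path)
    except (ValueError, OSError) as exc:
        raise VcfError(f"cannot parse VCF header of {path}: {exc}") from exc
    samples = list(vf.header.samples)
    with vf:
        for rec in vf:
            alts = rec.alts or ()
            gts = []
            for s in samples:
                try:
                    gts.append(rec.samples[s].get("GT", (None, None)))
                except Exception as exc:  # pragma: no cover - defensive
                    raise VcfError(
                        f"bad GT field at {rec.chrom}:{rec.pos} in {path}: {exc}"
                    ) from exc
            for ai, alt in enumerate(alts, start=1):
                if alt is None or _is_symbolic(alt):
                    if strict:
                        raise VcfError(
                            f"unsupported allele {alt!r} at {rec.chrom}:{rec.pos}"
                        )
                    n_skipped += 1
                    continue
                genotypes: list[Genotype] = []
                for gt in gts:
                    if gt is None or any(a is None for a in gt):
                        genotypes.append(None)
                    else:
                        genotypes.append(sum(1 for a in gt if a == ai))
                records.append(
                    VariantRecord(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        genotypes=genotypes,
                        caller=caller,
                        sample_names=tuple(samples),
                    )
                )
    if n_skipped:
        log.info("read_vcf(%s): skipped %d symbolic/breakend alleles", path, n_skipped)
    return VcfReadResult(records, samples, n_skipped)


def write_vcf(
    records: Iterable[VariantRecord],
    path,
    sample_names: Optional[Sequence[str]] = None,
    contigs: Optional[Mapping[str, int]] = None,
    source: str = "indelgwas",
) -> None:
    """Write records as a minimal VCF v4.2 text file (GT only)."""
    records = list(records)
    if sample_names is None:
        sample_names = list(records[0].sample_names) if records else []
    lines = ["##fileformat=VCFv4.2", f"##source={source}"]
    if contigs:
        for name, length in contigs.items():
            lines.append(f"##contig=<ID={name},length={length}>")
    else:
        seen: dict[str, None] = {}
        for r in records:
            seen.setdefault(r.chrom, None)
        for name in seen:
            lines.append(f"##contig=<ID={name}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
    if sample_names:
        header += ["FORMAT", *sample_names]
    lines.append("\t".join(header))
    for r in records:
        row = [r.chrom, str(r.pos), ".", r.ref, r.alt, ".", "PASS", "."]
        if sample_names:
            row.append("GT")
            row.extend(_GT_STRINGS[g] for g in r.genotypes)
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


def sort_records(records: Iterable[VariantRecord]) -> list:
    return sorted(records, key=lambda r: (r.chrom, r.pos, r.ref, r.alt))
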