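"""Consequence-term and severity annotation of indels against gene models.

A deliberately small effect predictor: for each transcript whose span (plus a
flank) contains a variant it emits one annotation carrying a set of
consequence terms, the maximum severity over those terms, and -- for inframe
coding indels -- an HGVS-style protein change.

Conventions (frozen here, documented in the README):

* flank for upstream/downstream terms: 5,000 bp;
* splice donor/acceptor: first/last 2 intronic bases, strand aware;
* splice region: 1-3 exonic or 3-8 intronic bases from a junction;
* an indel spanning an exon-intron boundary gets ``coding_sequence_variant``
  plus the splice term, never a frameshift call (frame undefined);
* ``stop_gained`` is only called when a premature stop codon appears within
  the codons touched by the edit itself (not in a scrambled frameshift tail).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from Bio.Seq import Seq
from Bio.SeqUtils import seq3

from .vario import NormalizedKey, fetch_seq, variant_class

log = logging.getLogger(__name__)

FLANK = 5000
SPLICE_SITE = 2       # intronic bases forming donor/acceptor sites
SPLICE_REGION_EXON = 3
SPLICE_REGION_INTRON = 8

# term -> severity, frozen
SEVERITY_MAP = {
    "intergenic_variant": "Modifier",
    "intron_variant": "Modifier",
    "downstream_gene_variant": "Modifier",
    "upstream_gene_variant": "Modifier",
    "non_coding_transcript_variant": "Modifier",
    "3_prime_UTR_variant": "Modifier",
    "NMD_transcript_variant": "Modifier",
    "splice_region_variant": "Low",
    "frameshift_variant": "High",
    "5_prime_UTR_variant": "Modifier",
    "non_coding_transcript_exon_variant": "Modifier",
    "inframe_deletion": "Moderate",
    "inframe_insertion": "Moderate",
    "coding_sequence_variant": "Modifier",
    "splice_acceptor_variant": "High",
    "splice_donor_variant": "High",
    "mature_miRNA_variant": "Modifier",
    "start_lost": "High",
    "stop_gained": "High",
    "protein_altering_variant": "Moderate",
    "stop_retained_variant": "Low",
    "stop_lost": "High",
    "incomplete_terminal_codon_variant": "Low",
}

_SEVERITY_RANK = {"Modifier": 0, "Low": 1, "Moderate": 2, "High": 3}


def severity_of(terms: Iterable[str]) -> str:
    """Maximum severity class over a non-empty set of consequence terms."""
    terms = list(terms)
    if not terms:
        raise ValueError("empty term set")
    best = "Modifier"
    for t in terms:
        if t not in SEVERITY_MAP:
            raise ValueError(f"unknown consequence term {t!r}")
        if _SEVERITY_RANK[SEVERITY_MAP[t]] > _SEVERITY_RANK[best]:
            best = SEVERITY_MAP[t]
    return best


@dataclass
class Transcript:
    transcript_id: str
    exons: list  # list[(start, end)] 1-based inclusive, sorted in genome order
    cds: list = field(default_factory=list)  # subset of exonic space
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        self.exons = sorted(tuple(e) for e in self.exons)
        self.cds = sorted(tuple(c) for c in self.cds)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 <= e1:
                raise ValueError(f"overlapping exons in {self.transcript_id}")

    @property
    def is_coding(self) -> bool:
        return bool(self.cds)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def introns(self) -> list:
        return [
            (e1 + 1, s2 - 1)
            for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])
            if s2 - e1 > 1
        ]

    @property
    def cds_len(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str  # "+" or "-"
    transcripts: list  # list[Transcript]
    biotype: str = "coding"

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")

    @property
    def start(self) -> int:
        return min(t.start for t in self.transcripts)

    @property
    def end(self) -> int:
        return max(t.end for t in self.transcripts)


@dataclass
class ConsequenceAnnotation:
    key: NormalizedKey
    gene_id: Optional[str]
    transcript_id: Optional[str]
    terms: set
    severity: str
    protein_change: Optional[str] = None


# ---------------------------------------------------------------------------
# interval helpers: the "touch span" of an edit
# ---------------------------------------------------------------------------


def _touch_span(key: NormalizedKey) -> tuple:
    """Genomic bases affected by the edit.

    Deletions touch the deleted bases; insertions touch the two bases flanking
    the insertion point (so a boundary insertion counts as spanning both
    features).
    """
    if len(key.ref) > len(key.alt):  # deletion
        return key.pos + 1, key.pos + len(key.ref) - 1
    return key.pos, key.pos + 1  # insertion


def _overlaps(a: int, b: int, s: int, e: int) -> bool:
    return a <= e and s <= b


# ---------------------------------------------------------------------------
# coding-sequence machinery
# ---------------------------------------------------------------------------


def _cds_sequence(tx: Transcript, chrom: str, strand: str, genome) -> str:
    seq = "".join(fetch_seq(genome, chrom, s, e) for s, e in tx.cds)
    if strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq


def _cds_offset(tx: Transcript, strand: str, gpos: int) -> Optional[int]:
    """0-based offset of genomic base ``gpos`` within the spliced CDS."""
    off = 0
    plus = None
    for s, e in tx.cds:
        if s <= gpos <= e:
            plus = off + (gpos - s)
            break
        off += e - s + 1
    if plus is None:
        return None
    if strand == "-":
        return tx.cds_len - 1 - plus
    return plus


def _translate(seq: str) -> str:
    usable = seq[: len(seq) - len(seq) % 3]
    if not usable:
        return ""
    return str(Seq(usable).translate())


def _apply_edit_to_cds(
    tx: Transcript, strand: str, key: NormalizedKey, cds_seq: str
) -> tuple:
    """Return (mutant_cds, edit_start, n_inserted) in transcript coordinates.

    Assumes the edit lies entirely within the CDS (checked by the caller).
    ``edit_start`` is the 0-based CDS offset where the mutant first differs.
    """
    if len(key.ref) > len(key.alt):  # deletion of genomic bases pos+1..pos+D
        d1, d2 = key.pos + 1, key.pos + len(key.ref) - 1
        o1 = _cds_offset(tx, strand, d1)
        o2 = _cds_offset(tx, strand, d2)
        lo, hi = min(o1, o2), max(o1, o2)
        mutant = cds_seq[:lo] + cds_seq[hi + 1 :]
        return mutant, lo, 0
    # insertion between pos and pos+1
    inserted = key.alt[1:]
    if strand == "+":
        at = _cds_offset(tx, strand, key.pos) + 1
        ins = inserted
    else:
        at = _cds_offset(tx, strand, key.pos + 1) + 1
        ins = str(Seq(inserted).reverse_complement())
    mutant = cds_seq[:at] + ins + cds_seq[at:]
    return mutant, at, len(ins)


def _aligned_diff(ref_aa: str, mut_aa: str) -> tuple:
    """Leftmost (suffix-maximal) alignment of two protein strings.

    Returns (prefix_len, deleted_segment, inserted_segment).
    """
    smax = 0
    lim = min(len(ref_aa), len(mut_aa))
    while smax < lim and ref_aa[len(ref_aa) - 1 - smax] == mut_aa[len(mut_aa) - 1 - smax]:
        smax += 1
    p = 0
    plim = min(len(ref_aa), len(mut_aa)) - smax
    while p < plim and ref_aa[p] == mut_aa[p]:
        p += 1
    return p, ref_aa[p : len(ref_aa) - smax], mut_aa[p : len(mut_aa) - smax]


def _hgvs_protein(ref_aa: str, mut_aa: str) -> Optional[str]:
    """HGVS-style p. notation for a pure deletion, duplication or insertion."""
    ref_aa = ref_aa.rstrip("*")
    mut_aa = mut_aa.rstrip("*")
    if ref_aa == mut_aa:
        return None
    p, dele, ins = _aligned_diff(ref_aa, mut_aa)
    if dele and not ins:
        first, last = p + 1, p + len(dele)
        if len(dele) == 1:
            return f"p.{seq3(dele[0])}{first}del"
        return f"p.{seq3(dele[0])}{first}_{seq3(dele[-1])}{last}del"
    if ins and not dele:
        # duplication if the inserted run copies the residues just after
        # (leftmost alignment) or just before the insertion point
        if ref_aa[p : p + len(ins)] == ins:
            first, last = p + 1, p + len(ins)
            if len(ins) == 1:
                return f"p.{seq3(ins[0])}{first}dup"
            return f"p.{seq3(ins[0])}{first}_{seq3(ins[-1])}{last}dup"
        if p >= len(ins) and ref_aa[p - len(ins) : p] == ins:
            first, last = p - len(ins) + 1, p
            if len(ins) == 1:
                return f"p.{seq3(ins[0])}{first}dup"
            return f"p.{seq3(ins[0])}{first}_{seq3(ins[-1])}{last}dup"
        ins3 = "".join(seq3(a) for a in ins)
        return f"p.{seq3(ref_aa[p - 1])}{p}_{seq3(ref_aa[p])}{p + 1}ins{ins3}"
    # delins
    first, last = p + 1, p + len(dele)
    ins3 = "".join(seq3(a) for a in ins)
    if len(dele) == 1:
        return f"p.{seq3(dele[0])}{first}delins{ins3}"
    return f"p.{seq3(dele[0])}{first}_{seq3(dele[-1])}{last}delins{ins3}"


def protein_change(key: NormalizedKey, gene: GeneModel, tx: Transcript, genome) -> Optional[str]:
    """Protein-level notation for an inframe coding indel; None otherwise."""
    if not tx.is_coding or key.indel_length % 3 != 0:
        return None
    span = _touch_span(key)
    if not _span_in_cds(tx, span, key):
        return None
    cds_seq = _cds_sequence(tx, gene.chrom, gene.strand, genome)
    if len(cds_seq) % 3 != 0:
        return None
    mutant, _, _ = _apply_edit_to_cds(tx, gene.strand, key, cds_seq)
    return _hgvs_protein(_translate(cds_seq), _translate(mutant))


def _span_in_cds(tx: Transcript, span: tuple, key: NormalizedKey) -> bool:
    """True if the edit falls entirely within one CDS interval."""
    a, b = span
    if len(key.ref) > len(key.alt):
        return any(s <= a and b <= e for s, e in tx.cds)
    # insertion: both flanking bases inside the same CDS interval
    return any(s <= a and b <= e for s, e in tx.cds)


# ---------------------------------------------------------------------------
# per-transcript annotation
# ---------------------------------------------------------------------------


def _splice_terms(tx: Transcript, strand: str, a: int, b: int) -> set:
    terms: set = set()
    for istart, iend in tx.introns:
        if strand == "+":
            donor = (istart, min(istart + SPLICE_SITE - 1, iend))
            acceptor = (max(iend - SPLICE_SITE + 1, istart), iend)
        else:
            donor = (max(iend - SPLICE_SITE + 1, istart), iend)
            acceptor = (istart, min(istart + SPLICE_SITE - 1, iend))
        if _overlaps(a, b, *donor):
            terms.add("splice_donor_variant")
        if _overlaps(a, b, *acceptor):
            terms.add("splice_acceptor_variant")
        # intronic splice region: 3..8 bases from either junction
        left_region = (istart + SPLICE_SITE, min(istart + SPLICE_REGION_INTRON - 1, iend))
        right_region = (max(iend - SPLICE_REGION_INTRON + 1, istart), iend - SPLICE_SITE)
        if (left_region[0] <= left_region[1] and _overlaps(a, b, *left_region)) or (
            right_region[0] <= right_region[1] and _overlaps(a, b, *right_region)
        ):
            terms.add("splice_region_variant")
    # exonic splice region: 1..3 exonic bases next to an intron
    introns = tx.introns
    for s, e in tx.exons:
        if any(iend + 1 == s for _, iend in introns) and _overlaps(
            a, b, s, min(s + SPLICE_REGION_EXON - 1, e)
        ):
            terms.add("splice_region_variant")
        if any(istart - 1 == e for istart, _ in introns) and _overlaps(
            a, b, max(e - SPLICE_REGION_EXON + 1, s), e
        ):
            terms.add("splice_region_variant")
    if {"splice_donor_variant", "splice_acceptor_variant"} & terms:
        terms.discard("splice_region_variant")
    return terms


def _utr_side(tx: Transcript, strand: str, a: int, b: int) -> Optional[str]:
    """5' or 3' UTR term for an exonic, non-CDS position."""
    cds_start, cds_end = tx.cds[0][0], tx.cds[-1][1]
    if b < cds_start:
        genomic_left = True
    elif a > cds_end:
        genomic_left = False
    else:
        return None
    if (strand == "+") == genomic_left:
        return "5_prime_UTR_variant"
    return "3_prime_UTR_variant"


def _coding_terms(
    key: NormalizedKey, gene: GeneModel, tx: Transcript, genome
) -> set:
    """Terms for an edit entirely inside the CDS."""
    terms: set = set()
    cds_seq = _cds_sequence(tx, gene.chrom, gene.strand, genome)
    length = key.indel_length
    is_del = len(key.ref) > len(key.alt)
    incomplete = len(cds_seq) % 3 != 0
    mutant, estart, n_ins = _apply_edit_to_cds(tx, gene.strand, key, cds_seq)

    if incomplete:
        # cannot reason about the terminal codon; flag if the edit touches it
        tail_start = len(cds_seq) - len(cds_seq) % 3
        if is_del:
            touches_tail = estart + length - 1 >= tail_start
        else:
            touches_tail = estart > tail_start
        if touches_tail:
            terms.add("incomplete_terminal_codon_variant")
        terms.add("frameshift_variant" if length % 3 else "coding_sequence_variant")
        return terms

    if length % 3:
        terms.add("frameshift_variant")
    else:
        terms.add("inframe_deletion" if is_del else "inframe_insertion")

    ref_aa = _translate(cds_seq)
    mut_aa = _translate(mutant)

    # start codon: edit disturbs the first codon and changes its bases
    if estart < 3 and (not mut_aa or mutant[:3] != cds_seq[:3]):
        terms.add("start_lost")

    # stop codon: a deletion disturbs ref offsets [estart, estart+length-1];
    # an insertion disturbs the stop only when placed between its bases
    if is_del:
        touches_stop = estart + length - 1 >= len(cds_seq) - 3
    else:
        touches_stop = estart > len(cds_seq) - 3
    if touches_stop:
        if "*" in mut_aa:
            terms.add("stop_retained_variant")
        else:
            terms.add("stop_lost")
    else:
        # premature stop only if it appears within the codons touched by the
        # edit itself (junction codons for deletions, inserted codons for
        # insertions) and strictly before the mutant's final codon
        cs = estart // 3
        ce = (estart + n_ins) // 3
        window = mut_aa[cs : ce + 1]
        if "*" in window and cs + window.index("*") < len(mut_aa) - 1:
            terms.add("stop_gained")

    # delins at protein level (inframe edit that also substitutes residues)
    if length % 3 == 0 and not touches_stop and "stop_gained" not in terms:
        _, dele, ins = _aligned_diff(ref_aa.rstrip("*"), mut_aa.rstrip("*"))
        if dele and ins:
            terms.add("protein_altering_variant")
    return terms


def _annotate_transcript(
    key: NormalizedKey, gene: GeneModel, tx: Transcript, genome, flank: int
) -> Optional[ConsequenceAnnotation]:
    a, b = _touch_span(key)
    strand = gene.strand
    if b < tx.start - flank or a > tx.end + flank:
        return None
    terms: set = set()
    pchange: Optional[str] = None

    if b < tx.start or a > tx.end:
        genomic_left = b < tx.start
        if (strand == "+") == genomic_left:
            terms.add("upstream_gene_variant")
        else:
            terms.add("downstream_gene_variant")
    else:
        exon_hit = any(_overlaps(a, b, s, e) for s, e in tx.exons)
        intron_hit = any(_overlaps(a, b, s, e) for s, e in tx.introns)
        terms |= _splice_terms(tx, strand, a, b)
        if not tx.is_coding:
            if exon_hit:
                terms.add("non_coding_transcript_exon_variant")
            else:
                terms.add("intron_variant")
                terms.add("non_coding_transcript_variant")
            if tx.biotype == "miRNA" and exon_hit:
                terms.add("mature_miRNA_variant")
        elif exon_hit and intron_hit:
            # spans an exon-intron boundary: frame undefined
            if any(_overlaps(a, b, s, e) for s, e in tx.cds):
                terms.add("coding_sequence_variant")
            else:
                utr = _utr_side(tx, strand, a, a)  # side of the exonic part
                if utr:
                    terms.add(utr)
        elif intron_hit:
            terms.add("intron_variant")
        else:
            cds_hit = any(_overlaps(a, b, s, e) for s, e in tx.cds)
            if not cds_hit:
                utr = _utr_side(tx, strand, a, b)
                if utr:
                    terms.add(utr)
                else:
                    terms.add("coding_sequence_variant")
            elif _span_in_cds(tx, (a, b), key):
                terms |= _coding_terms(key, gene, tx, genome)
                if key.indel_length % 3 == 0:
                    pchange = protein_change(key, gene, tx, genome)
            else:
                # partially CDS (UTR/CDS boundary within an exon)
                terms.add("coding_sequence_variant")
                cds_start, cds_end = tx.cds[0][0], tx.cds[-1][1]
                start_codon = (
                    (cds_start, cds_start + 2) if strand == "+" else (cds_end - 2, cds_end)
                )
                if len(key.ref) > len(key.alt) and _overlaps(a, b, *start_codon):
                    terms.add("start_lost")
                utr = _utr_side(tx, strand, a, a) or _utr_side(tx, strand, b, b)
                if utr:
                    terms.add(utr)
        if tx.biotype == "nmd":
            terms.add("NMD_transcript_variant")
    if not terms:
        return None
    return ConsequenceAnnotation(
        key=key,
        gene_id=gene.gene_id,
        transcript_id=tx.transcript_id,
        terms=terms,
        severity=severity_of(terms),
        protein_change=pchange,
    )


def annotate(
    key: NormalizedKey,
    genes: Sequence[GeneModel],
    genome,
    flank: int = FLANK,
) -> list:
    """Annotate one normalized variant against all gene models.

    Returns one :class:`ConsequenceAnnotation` per overlapping transcript (its
    span plus ``flank``); a variant hitting nothing yields a single intergenic
    annotation.
    """
    if hasattr(genome, "chromosomes"):
        known = key.chrom in genome.chromosomes
    else:
        try:
            genome[key.chrom]
            known = True
        except KeyError:
            known = False
    if not known:
        raise ValueError(f"variant on unknown chromosome {key.chrom!r}")
    out = []
    for gene in genes:
        if gene.chrom != key.chrom:
            continue
        for tx in gene.transcripts:
            ann = _annotate_transcript(key, gene, tx, genome, flank)
            if ann is not None:
                out.append(ann)
    if not out:
        out.append(
            ConsequenceAnnotation(
                key=key,
                gene_id=None,
                transcript_id=None,
                terms={"intergenic_variant"},
                severity="Modifier",
            )
        )
    return out


def annotate_all(keys, genes, genome, flank: int = FLANK) -> list:
    out = []
    for k in keys:
        out.extend(annotate(k, genes, genome, flank))
    return out
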