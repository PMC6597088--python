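"""Shared test helpers: independent oracles and hand-built gene fixtures.

Everything here is deliberately written from first principles (string edits,
enumeration, direct translation) so that it stays independent of the package
code paths it is used to check.
"""

from __future__ import annotations

import numpy as np
from Bio.Seq import Seq

from indelgwas.consequence import GeneModel, Transcript
from indelgwas.syndata.genome import SimulatedGenome


# ---------------------------------------------------------------------------
# string-edit oracles
# ---------------------------------------------------------------------------


def apply_edit(seq: str, pos: int, ref: str, alt: str) -> str:
    """Apply a VCF-style edit to a sequence string (1-based pos)."""
    assert seq[pos - 1 : pos - 1 + len(ref)] == ref, "oracle: ref mismatch"
    return seq[: pos - 1] + alt + seq[pos - 1 + len(ref) :]


def brute_leftmost(seq: str, pos: int, ref: str, alt: str, window: int = 80):
    """Leftmost minimal representation found by exhaustive enumeration.

    Tries every candidate anchor position in a window and keeps the first
    (leftmost) whose single-base-anchored representation reproduces the same
    mutated sequence.
    """
    target = apply_edit(seq, pos, ref, alt)
    ldiff = len(alt) - len(ref)
    for p in range(max(1, pos - window), pos + window + 1):
        if ldiff < 0:  # deletion
            cref = seq[p - 1 : p - 1 + 1 - ldiff]
            calt = seq[p - 1]
        elif ldiff > 0:  # insertion: inserted bases read off the target string
            cref = seq[p - 1]
            calt = cref + target[p : p + ldiff]
        else:  # substitution
            cref = seq[p - 1]
            calt = target[p - 1]
        if len(cref) != len(calt) and (len(cref) < 1 or len(calt) < 1):
            continue
        if cref == calt:
            continue
        try:
            if apply_edit(seq, p, cref, calt) == target:
                return p, cref, calt
        except AssertionError:
            continue
    raise AssertionError("oracle: no equivalent representation found")


def equivalent(seq: str, rep_a: tuple, rep_b: tuple) -> bool:
    """True when two (pos, ref, alt) representations yield the same mutant."""
    return apply_edit(seq, *rep_a) == apply_edit(seq, *rep_b)


def translate(seq: str) -> str:
    usable = seq[: len(seq) - len(seq) % 3]
    return str(Seq(usable).translate()) if usable else ""


# ---------------------------------------------------------------------------
# hand-built toy gene (both strands share the same transcript content)
# ---------------------------------------------------------------------------

UTR5 = "TTCTTCCTTC"                      # 10 bases
UTR3 = "GGTTGGTTGGTT"                    # 12 bases
_BODY_CODONS = [
    "GCT", "AAA", "GGG", "TGC", "CTG", "GAT", "CCA", "TTT", "CAG", "ATC",
    "GAA", "CGT", "ACC", "GTG", "TAC", "CAT", "AGC", "CTC", "AAC", "GGG",
    "ATT", "GAC", "CCT", "GCA", "AGA", "GTT", "TCC",
]
CDS_SEQ = "ATG" + "".join(_BODY_CODONS) + "TCA" + "TGA"  # 30 codons, 90 bases
TRANSCRIPT = UTR5 + CDS_SEQ + UTR3                        # 112 bases

# exon sizes in transcript order; canonical GT..AG introns between them.
# The filler is chosen so that deletions of the donor/acceptor dinucleotides
# are not left-shiftable (their normalized keys stay on the splice sites).
EXON_SIZES = (40, 40, 32)
INTRON_TX = "GT" + "CT" * 23 + "AG"  # 50 bases, transcript orientation
INTRON_LEN = len(INTRON_TX)
PAD = 6000


def _fixed_pad(n: int, seed: int) -> str:
    rng = np.random.default_rng(seed)
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def toy_gene(strand: str = "+", chrom: str = "chrZ"):
    """A deterministic 3-exon coding gene on either strand.

    Returns ``(SimulatedGenome, GeneModel)``.  The spliced transcript is
    identical for both strands; on '-' the genomic layout is mirrored.
    """
    gene_len = sum(EXON_SIZES) + INTRON_LEN * (len(EXON_SIZES) - 1)
    gs = PAD + 1

    # transcript-order exon intervals in "gene-local transcript layout"
    tx_bounds = []
    off = 0
    for sz in EXON_SIZES:
        tx_bounds.append((off, off + sz - 1))
        off += sz

    if strand == "+":
        genomic_gene = ""
        g = 0
        exons = []
        t = 0
        for i, sz in enumerate(EXON_SIZES):
            exons.append((gs + g, gs + g + sz - 1))
            genomic_gene += TRANSCRIPT[t : t + sz]
            t += sz
            g += sz
            if i < len(EXON_SIZES) - 1:
                genomic_gene += INTRON_TX
                g += INTRON_LEN
    else:
        # mirror: transcript runs right-to-left on the genome
        genomic_gene = ""
        g = 0
        exons = []
        sizes_genomic = EXON_SIZES[::-1]
        rc = str(Seq(TRANSCRIPT).reverse_complement())
        t = 0
        for i, sz in enumerate(sizes_genomic):
            exons.append((gs + g, gs + g + sz - 1))
            genomic_gene += rc[t : t + sz]
            t += sz
            g += sz
            if i < len(sizes_genomic) - 1:
                genomic_gene += str(Seq(INTRON_TX).reverse_complement())
                g += INTRON_LEN

    seq = _fixed_pad(PAD, 1) + genomic_gene + _fixed_pad(PAD, 2)

    # CDS transcript offsets [10, 99]; map back to genomic intervals.
    # On '-' the i-th genomic exon is the (n-1-i)-th transcript exon and runs
    # in the opposite direction within the exon.
    cds_lo, cds_hi = 10, 10 + len(CDS_SEQ) - 1
    cds_intervals = []
    n_ex = len(EXON_SIZES)
    for i, (es, ee) in enumerate(exons):
        j = i if strand == "+" else n_ex - 1 - i
        a, b = tx_bounds[j]
        lo, hi = max(a, cds_lo), min(b, cds_hi)
        if lo > hi:
            continue
        if strand == "+":
            cds_intervals.append((es + (lo - a), es + (hi - a)))
        else:
            cds_intervals.append((es + (b - hi), es + (b - lo)))
    tx = Transcript("toy.t1", exons=exons, cds=sorted(cds_intervals))
    gene = GeneModel("toy", chrom, strand, [tx])
    genome = SimulatedGenome(chromosomes={chrom: seq}, gene_models=[gene])
    # sanity: spliced CDS translates cleanly
    spliced = "".join(seq[s - 1 : e] for s, e in tx.cds)
    if strand == "-":
        spliced = str(Seq(spliced).reverse_complement())
    assert spliced == CDS_SEQ
    return genome, gene


def cds_genomic_pos(gene: GeneModel, cds_offset: int) -> int:
    """Genomic position (1-based) of 0-based CDS offset, transcript orientation."""
    tx = gene.transcripts[0]
    total = tx.cds_len
    if gene.strand == "+":
        off = cds_offset
        for s, e in tx.cds:
            sz = e - s + 1
            if off < sz:
                return s + off
            off -= sz
    else:
        off = total - 1 - cds_offset  # plus-strand offset
        for s, e in tx.cds:
            sz = e - s + 1
            if off < sz:
                return s + off
            off -= sz
    raise AssertionError("CDS offset out of range")


def cds_deletion(genome, gene, cds_start: int, length: int):
    """Raw (pos, ref, alt) deleting CDS offsets [cds_start, cds_start+length-1]."""
    seq = genome.chromosomes[gene.chrom]
    g = [cds_genomic_pos(gene, o) for o in range(cds_start, cds_start + length)]
    lo, hi = min(g), max(g)
    assert hi - lo + 1 == length, "deletion spans an intron"
    pos = lo - 1
    return pos, seq[pos - 1 : hi], seq[pos - 1]


def cds_insertion(genome, gene, cds_after: int, ins_tx: str):
    """Raw (pos, ref, alt) inserting ``ins_tx`` (transcript orientation) after
    CDS offset ``cds_after``."""
    seq = genome.chromosomes[gene.chrom]
    if gene.strand == "+":
        pos = cds_genomic_pos(gene, cds_after)
        ins = ins_tx
    else:
        pos = cds_genomic_pos(gene, cds_after) - 1
        ins = str(Seq(ins_tx).reverse_complement())
    ref = seq[pos - 1]
    return pos, ref, ref + ins


def mutant_cds(cds_start_or_after, edit: str, payload) -> str:
    """CDS-space edit oracle: deletion ('del', start, length) or insertion
    ('ins', after, seq)."""
    if edit == "del":
        start, length = cds_start_or_after, payload
        return CDS_SEQ[:start] + CDS_SEQ[start + length :]
    after, ins = cds_start_or_after, payload
    return CDS_SEQ[: after + 1] + ins + CDS_SEQ[after + 1 :]


def brute_bh(p):
    """Independent step-up BH implementation (quadratic, by the definition)."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [None] * m
    for rank, i in enumerate(order, start=1):
        q[i] = min(
            min(p[order[j - 1]] * m / j for j in range(rank, m + 1)), 1.0
        )
    return q
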