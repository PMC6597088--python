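import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from indelgwas.consequence import (
    SEVERITY_MAP,
    ConsequenceAnnotation,
    GeneModel,
    Transcript,
    annotate,
    protein_change,
    severity_of,
)
from indelgwas.vario import normalize
from indelgwas.syndata.genome import SimulatedGenome

from util import (
    CDS_SEQ,
    cds_deletion,
    cds_genomic_pos,
    cds_insertion,
    mutant_cds,
    toy_gene,
    translate,
)


def ann_terms(genome, gene, raw):
    key = normalize(("chrZ", *raw), genome)
    anns = annotate(key, [gene], genome)
    assert len(anns) == 1
    return anns[0]


@pytest.fixture(scope="module", params=["+", "-"])
def toy(request):
    genome, gene = toy_gene(strand=request.param)
    return genome, gene


class TestTruthTable:
    """Planted cases for every term class, checked against the CDS-space
    sequence-edit + translation oracle where coding logic is involved."""

    def test_intergenic(self, toy):
        genome, gene = toy
        seq = genome.chromosomes["chrZ"]
        pos = 300  # > 5 kb from the gene
        a = ann_terms(genome, gene, (pos, seq[pos - 1 : pos + 1], seq[pos - 1]))
        assert a.terms == {"intergenic_variant"} and a.severity == "Modifier"

    def test_upstream_downstream(self, toy):
        genome, gene = toy
        seq = genome.chromosomes["chrZ"]
        tx = gene.transcripts[0]
        left = tx.start - 1000
        right = tx.end + 1000
        a_left = ann_terms(genome, gene, (left, seq[left - 1 : left + 1], seq[left - 1]))
        a_right = ann_terms(genome, gene, (right, seq[right - 1 : right + 1], seq[right - 1]))
        if gene.strand == "+":
            assert a_left.terms == {"upstream_gene_variant"}
            assert a_right.terms == {"downstream_gene_variant"}
        else:
            assert a_left.terms == {"downstream_gene_variant"}
            assert a_right.terms == {"upstream_gene_variant"}

    def test_intron_middle(self, toy):
        genome, gene = toy
        seq = genome.chromosomes["chrZ"]
        istart, iend = gene.transcripts[0].introns[0]
        mid = (istart + iend) // 2
        a = ann_terms(genome, gene, (mid, seq[mid - 1 : mid + 1], seq[mid - 1]))
        assert "intron_variant" in a.terms
        assert not a.terms & {"splice_region_variant", "splice_donor_variant",
                              "splice_acceptor_variant"}
        assert a.severity == "Modifier"

    def test_splice_donor_and_acceptor(self, toy):
        genome, gene = toy
        seq = genome.chromosomes["chrZ"]
        istart, iend = gene.transcripts[0].introns[0]
        first2 = istart  # deletion hitting the first 2 intronic bases
        a = ann_terms(genome, gene, (first2 - 1, seq[first2 - 2 : first2 + 1], seq[first2 - 2]))
        last2 = iend - 1
        b = ann_terms(genome, gene, (last2 - 1, seq[last2 - 2 : last2 + 1], seq[last2 - 2]))
        if gene.strand == "+":
            assert "splice_donor_variant" in a.terms and a.severity == "High"
            assert "splice_acceptor_variant" in b.terms and b.severity == "High"
        else:
            assert "splice_acceptor_variant" in a.terms
            assert "splice_donor_variant" in b.terms

    def test_splice_region_intronic(self, toy):
        genome, gene = toy
        seq = genome.chromosomes["chrZ"]
        istart, _ = gene.transcripts[0].introns[0]
        p = istart + 4  # 5th intronic base: inside 3-8 window
        a = ann_terms(genome, gene, (p, seq[p - 1 : p + 1], seq[p - 1]))
        assert {"splice_region_variant", "intron_variant"} <= a.terms
        assert a.severity == "Low"

    def test_utr5_and_utr3(self, toy):
        genome, gene = toy
        seq = genome.chromosomes["chrZ"]
        # 5' UTR: transcript offsets 4..6; 3' UTR: offsets 104..106
        utr5_g = sorted(
            _transcript_genomic_pos(gene, o) for o in (4, 5, 6)
        )
        utr3_g = sorted(
            _transcript_genomic_pos(gene, o) for o in (104, 105, 106)
        )
        p = utr5_g[0]
        a = ann_terms(genome, gene, (p - 1, seq[p - 2 : p + 1], seq[p - 2]))
        assert "5_prime_UTR_variant" in a.terms and a.severity == "Modifier"
        p = utr3_g[0]
        b = ann_terms(genome, gene, (p - 1, seq[p - 2 : p + 1], seq[p - 2]))
        assert "3_prime_UTR_variant" in b.terms and b.severity == "Modifier"

    def test_frameshift(self, toy):
        genome, gene = toy
        a = ann_terms(genome, gene, cds_deletion(genome, gene, 45, 1))
        assert "frameshift_variant" in a.terms and a.severity == "High"
        mut = mutant_cds(45, "del", 1)
        assert len(mut) % 3 != 0  # oracle agrees frame is broken

    def test_inframe_deletion_with_protein_change(self, toy):
        genome, gene = toy
        a = ann_terms(genome, gene, cds_deletion(genome, gene, 45, 3))
        assert "inframe_deletion" in a.terms and a.severity == "Moderate"
        # oracle: codon-aligned removal of codon 16 (offset 45)
        ref_aa = translate(CDS_SEQ).rstrip("*")
        mut_aa = translate(mutant_cds(45, "del", 3)).rstrip("*")
        assert len(ref_aa) - len(mut_aa) == 1
        assert a.protein_change is not None and a.protein_change.endswith("del")

    def test_inframe_insertion(self, toy):
        genome, gene = toy
        a = ann_terms(genome, gene, cds_insertion(genome, gene, 47, "AAA"))
        assert "inframe_insertion" in a.terms and a.severity == "Moderate"

    def test_start_lost(self, toy):
        genome, gene = toy
        a = ann_terms(genome, gene, cds_deletion(genome, gene, 0, 3))
        assert "start_lost" in a.terms and a.severity == "High"
        assert not translate(mutant_cds(0, "del", 3)).startswith("M")

    def test_stop_gained_by_insertion(self, toy):
        genome, gene = toy
        # insert TAA after codon boundary (offset 44 ends codon 15)
        a = ann_terms(genome, gene, cds_insertion(genome, gene, 44, "TAA"))
        assert "stop_gained" in a.terms and a.severity == "High"
        mut_aa = translate(mutant_cds(44, "ins", "TAA"))
        assert "*" in mut_aa[:-1]  # oracle sees a premature stop

    def test_stop_lost(self, toy):
        genome, gene = toy
        # delete the stop codon (CDS offsets 87-89)
        a = ann_terms(genome, gene, cds_deletion(genome, gene, 87, 3))
        assert "stop_lost" in a.terms and a.severity == "High"
        assert "*" not in translate(mutant_cds(87, "del", 3))

    def test_stop_retained_frameshift_insertion_in_stop(self, toy):
        genome, gene = toy
        # stop codon is TGA (offsets 87-89); inserting A between T and G reads
        # TAG at the terminal codon: frameshift + stop retained
        a = ann_terms(genome, gene, cds_insertion(genome, gene, 87, "A"))
        mut = mutant_cds(87, "ins", "A")
        assert translate(mut).endswith("*")  # oracle: still terminates
        assert {"frameshift_variant", "stop_retained_variant"} <= a.terms
        assert a.severity == "High"

    def test_inframe_deletion_beside_stop_keeps_plain_terms(self, toy):
        genome, gene = toy
        # deleting the penultimate codon leaves the stop untouched after
        # normalization: inframe_deletion only, no stop term
        a = ann_terms(genome, gene, cds_deletion(genome, gene, 85, 3))
        assert translate(mutant_cds(85, "del", 3)).endswith("*")
        assert "inframe_deletion" in a.terms
        assert "stop_gained" not in a.terms and "stop_lost" not in a.terms

    def test_boundary_deletion_no_frameshift(self, toy):
        genome, gene = toy
        seq = genome.chromosomes["chrZ"]
        # deletion spanning the first exon/intron boundary
        (e1s, e1e) = gene.transcripts[0].exons[0]
        pos = e1e - 2
        a = ann_terms(genome, gene, (pos, seq[pos - 1 : pos + 5], seq[pos - 1]))
        assert "frameshift_variant" not in a.terms
        assert "coding_sequence_variant" in a.terms
        assert a.terms & {"splice_donor_variant", "splice_acceptor_variant"}

    def test_noncoding_transcript(self):
        genome, gene = toy_gene("+")
        tx = gene.transcripts[0]
        nc = GeneModel(
            "nc1", "chrZ", "+",
            [Transcript("nc1.t1", exons=tx.exons, cds=[], biotype="lncRNA")],
        )
        seq = genome.chromosomes["chrZ"]
        p = tx.exons[0][0] + 5
        key = normalize(("chrZ", p, seq[p - 1 : p + 1], seq[p - 1]), genome)
        a = annotate(key, [nc], genome)[0]
        assert "non_coding_transcript_exon_variant" in a.terms
        istart, iend = tx.introns[0]
        mid = (istart + iend) // 2
        key = normalize(("chrZ", mid, seq[mid - 1 : mid + 1], seq[mid - 1]), genome)
        b = annotate(key, [nc], genome)[0]
        assert {"non_coding_transcript_variant", "intron_variant"} <= b.terms

    def test_incomplete_terminal_codon(self):
        genome, gene = toy_gene("+")
        tx = gene.transcripts[0]
        # truncate annotated CDS by one base: length 89, not divisible by 3
        cds = list(tx.cds)
        s, e = cds[-1]
        cds[-1] = (s, e - 1)
        trunc = GeneModel(
            "trunc", "chrZ", "+",
            [Transcript("trunc.t1", exons=tx.exons, cds=cds)],
        )
        raw = cds_deletion(genome, gene, 86, 3)  # overlaps the partial codon
        key = normalize(("chrZ", *raw), genome)
        a = annotate(key, [trunc], genome)[0]
        assert "incomplete_terminal_codon_variant" in a.terms

    def test_annotation_count_with_overlapping_transcripts(self, toy):
        genome, gene = toy
        tx = gene.transcripts[0]
        two_tx = GeneModel(
            gene.gene_id, "chrZ", gene.strand,
            [tx, Transcript("toy.t2", exons=tx.exons, cds=tx.cds)],
        )
        raw = cds_deletion(genome, gene, 45, 3)
        key = normalize(("chrZ", *raw), genome)
        anns = annotate(key, [two_tx], genome)
        assert len(anns) == 2  # one line per co-located transcript


def _transcript_genomic_pos(gene, tx_offset):
    """Genomic position of a transcript offset (0-based) for the toy gene."""
    tx = gene.transcripts[0]
    sizes = [e - s + 1 for s, e in tx.exons]
    if gene.strand == "+":
        off = tx_offset
        for (s, e), sz in zip(tx.exons, sizes):
            if off < sz:
                return s + off
            off -= sz
    else:
        total = sum(sizes)
        off = total - 1 - tx_offset
        for (s, e), sz in zip(tx.exons, sizes):
            if off < sz:
                return s + off
            off -= sz
    raise AssertionError


class TestFrameshiftLaw:
    def test_frameshift_iff_length_not_multiple_of_three(self, toy):
        genome, gene = toy
        rng = np.random.default_rng(99)
        n_checked = 0
        while n_checked < 200:
            length = int(rng.integers(1, 7))
            start = int(rng.integers(6, 80 - length))
            is_del = rng.random() < 0.5
            try:
                if is_del:
                    raw = cds_deletion(genome, gene, start, length)
                else:
                    ins = "".join("ACGT"[b] for b in rng.integers(0, 4, size=length))
                    raw = cds_insertion(genome, gene, start, ins)
            except AssertionError:
                continue  # spans an intron; not a pure-CDS case
            key = normalize(("chrZ", *raw), genome)
            anns = annotate(key, [gene], genome)
            terms = anns[0].terms
            non_cds = {
                "coding_sequence_variant", "intron_variant", "splice_donor_variant",
                "splice_acceptor_variant", "splice_region_variant",
                "5_prime_UTR_variant", "3_prime_UTR_variant",
            }
            if not terms & non_cds:  # normalized edit stayed fully in CDS
                if length % 3:
                    assert "frameshift_variant" in terms, (raw, terms)
                else:
                    assert "frameshift_variant" not in terms, (raw, terms)
                n_checked += 1


class TestSeverity:
    def test_map_frozen(self):
        expected = {
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
        assert SEVERITY_MAP == expected

    def test_max_rule_examples(self):
        assert severity_of({"frameshift_variant", "stop_retained_variant"}) == "High"
        assert severity_of({"intron_variant"}) == "Modifier"
        assert severity_of({"splice_region_variant", "intron_variant"}) == "Low"

    def test_unknown_term_rejected(self):
        with pytest.raises(ValueError):
            severity_of({"made_up_term"})
        with pytest.raises(ValueError):
            severity_of(set())

    @settings(max_examples=100, deadline=None)
    @given(
        base=st.sets(st.sampled_from(sorted(SEVERITY_MAP)), min_size=1, max_size=4),
        extra=st.sampled_from(sorted(SEVERITY_MAP)),
    )
    def test_monotone_under_union(self, base, extra):
        rank = {"Modifier": 0, "Low": 1, "Moderate": 2, "High": 3}
        assert rank[severity_of(base | {extra})] >= rank[severity_of(base)]


class TestProteinChange:
    def _mini(self, cds):
        seq = "GGGGG" + "TTTTT" + cds + "CCCCC" + "GGGGG"
        start = 11
        tx = Transcript("m.t1", exons=[(start, start + len(cds) - 1)],
                        cds=[(start, start + len(cds) - 1)])
        gene = GeneModel("mini", "c", "+", [tx])
        genome = SimulatedGenome({"c": seq}, [gene])
        return genome, gene, tx, start

    def test_single_codon_deletion(self):
        genome, gene, tx, start = self._mini("ATGGCTGCATAA")
        # delete codon 2 ("GCT"): genomic bases start+3 .. start+5
        seq = genome.chromosomes["c"]
        pos = start + 2
        key = normalize(("c", pos, seq[pos - 1 : pos + 3], seq[pos - 1]), genome)
        assert protein_change(key, gene, tx, genome) == "p.Ala2del"

    def test_codon_duplication(self):
        genome, gene, tx, start = self._mini("ATGGCTGCATAA")
        seq = genome.chromosomes["c"]
        pos = start + 5  # insert "GCT" right after codon 2
        key = normalize(("c", pos, seq[pos - 1], seq[pos - 1] + "GCT"), genome)
        assert protein_change(key, gene, tx, genome) == "p.Ala2dup"

    def test_intronic_returns_none(self):
        genome, gene = toy_gene("+")
        tx = gene.transcripts[0]
        istart, iend = tx.introns[0]
        mid = (istart + iend) // 2
        seq = genome.chromosomes["chrZ"]
        key = normalize(("chrZ", mid, seq[mid - 1 : mid + 1], seq[mid - 1]), genome)
        assert protein_change(key, gene, tx, genome) is None

    def test_c1qtnf12_style_position(self):
        # 3-base inframe deletion removing alanine N of a longer protein
        body = "GCT" * 200  # poly-Ala
        genome, gene, tx, start = self._mini("ATG" + body + "TAA")
        seq = genome.chromosomes["c"]
        pos = start + 2 + 3 * 100  # delete one Ala codon mid-protein
        key = normalize(("c", pos, seq[pos - 1 : pos + 3], seq[pos - 1]), genome)
        pc = protein_change(key, gene, tx, genome)
        assert pc is not None and pc.startswith("p.Ala") and pc.endswith("del")


def test_unknown_chromosome_rejected(small_genome):
    from indelgwas.vario import NormalizedKey

    with pytest.raises(ValueError):
        annotate(NormalizedKey("chr99", 100, "AT", "A"), small_genome.gene_models,
                 small_genome)


def test_strand_symmetry_same_terms():
    """The same transcript-space edits produce the same term sets on both
    strands (the genomic layout is mirrored)."""
    gp, genep = toy_gene("+")
    gm, genem = toy_gene("-")
    cases = [
        ("del", 45, 1), ("del", 45, 3), ("del", 0, 3), ("del", 87, 3),
        ("ins", 44, "TAA"), ("ins", 47, "AAA"),
    ]
    for kind, a, b in cases:
        outs = []
        for genome, gene in ((gp, genep), (gm, genem)):
            if kind == "del":
                raw = cds_deletion(genome, gene, a, b)
            else:
                raw = cds_insertion(genome, gene, a, b)
            key = normalize(("chrZ", *raw), genome)
            outs.append(annotate(key, [gene], genome)[0].terms)
        assert outs[0] == outs[1], (kind, a, b, outs)
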