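import numpy as np
import pytest
from hypothesis import given, settings, strategies as st_h

from scisoqtl import annotate
from scisoqtl.models import GenomicInterval

from conftest import make_transcript


class TestJunctions:
    def test_two_exon_plus_strand(self, two_exon_plus):
        (j,) = annotate.extract_junctions(two_exon_plus)
        assert (j.donor, j.acceptor) == (201, 299)
        assert (j.intron_start, j.intron_end) == (201, 299)

    def test_single_exon_empty(self):
        m = make_transcript("s", [(100, 400)])
        assert annotate.extract_junctions(m) == []

    def test_minus_strand_donor_is_high_coordinate(self):
        m = make_transcript("neg", [(100, 200), (300, 400)], strand="-")
        (j,) = annotate.extract_junctions(m)
        assert (j.donor, j.acceptor) == (299, 201)

    def test_dinucleotide_annotation(self):
        seq = "N" * 200 + "GT" + "N" * 95 + "AG" + "N" * 200
        m = make_transcript("t", [(100, 200), (300, 400)])
        (j,) = annotate.extract_junctions(m, genome={"chr1": seq})
        assert j.dinucleotides == "GT-AG"
        assert annotate.is_canonical(j) is True


class TestStructure:
    def test_identical_chain_is_fsm(self, five_exon_ref):
        cand = make_transcript(
            "c", [(150, 200), (300, 400), (500, 600), (700, 800), (900, 950)]
        )
        assert annotate.classify_structure(cand, [five_exon_ref]) == "FSM"

    def test_suffix_chain_is_ism(self, five_exon_ref):
        cand = make_transcript("c", [(520, 600), (700, 800), (900, 1000)])
        assert annotate.classify_structure(cand, [five_exon_ref]) == "ISM"

    def test_known_sites_novel_combination_is_nic(self, five_exon_ref):
        # skips exon 2: junction donor 201 + acceptor 499 both known, pair novel
        cand = make_transcript("c", [(100, 200), (500, 600), (700, 800), (900, 1000)])
        assert annotate.classify_structure(cand, [five_exon_ref]) == "NIC"

    def test_shifted_donor_is_nnc(self, five_exon_ref):
        cand = make_transcript(
            "c", [(100, 205), (300, 400), (500, 600), (700, 800), (900, 1000)]
        )
        assert annotate.classify_structure(cand, [five_exon_ref]) == "NNC"
        assert annotate.nnc_witness(cand, [five_exon_ref]) == 206

    def test_empty_reference_errors(self, five_exon_ref):
        with pytest.raises(ValueError, match="empty reference"):
            annotate.classify_structure(five_exon_ref, [])

    def test_mono_exon_contained_is_fsm_else_other(self):
        ref = make_transcript("r", [(100, 500)])
        inside = make_transcript("c1", [(150, 400)])
        outside = make_transcript("c2", [(600, 700)])
        assert annotate.classify_structure(inside, [ref]) == "FSM"
        assert annotate.classify_structure(outside, [ref]) == "other"

    def test_identity_law_on_generated_models(self):
        from scisoqtl import syndata

        models, _, _ = syndata.simulate_transcriptome(5, 4, seed=1)
        for m in models:
            if len(m.exons) > 1:
                assert annotate.classify_structure(m, [m]) == "FSM"

    def test_generated_categories_match_design(self):
        from scisoqtl import syndata

        models, refs, expected = syndata.simulate_transcriptome(8, 6, seed=2)
        ref_by_gene = {r.gene_id: [r] for r in refs}
        for m in models:
            if m.transcript_id in expected:
                got = annotate.classify_structure(m, ref_by_gene[m.gene_id])
                assert got == expected[m.transcript_id], m.transcript_id


class TestNmd:
    def _fixture(self, stop_upstream_nt):
        # two exons of 100 nt (+): last junction at spliced position 101
        return make_transcript(
            "t", [(1000, 1099), (1200, 1299)],
            cds_start=1000, cds_end=1000 + (101 - stop_upstream_nt) - 1,
        )

    def test_60nt_upstream_sensitive(self):
        assert annotate.classify_nmd(self._fixture(60)) is True

    def test_exact_50nt_boundary(self):
        assert annotate.classify_nmd(self._fixture(50)) is True
        assert annotate.classify_nmd(self._fixture(49)) is False

    def test_single_exon_insensitive(self):
        m = make_transcript("t", [(100, 400)], cds_start=120, cds_end=300)
        assert annotate.classify_nmd(m) is False

    def test_minus_strand_boundary(self):
        # two exons of 100 nt (-): terminal exon is the genomic-first one
        def fixture(up):
            return make_transcript(
                "t", [(1000, 1099), (1200, 1299)], strand="-",
                cds_start=1200 + up - 1, cds_end=1290,
            )
        assert annotate.classify_nmd(fixture(50)) is True
        assert annotate.classify_nmd(fixture(49)) is False

    def test_cds_outside_exons_errors(self):
        m = make_transcript(
            "t", [(1000, 1099), (1200, 1299)], cds_start=1000, cds_end=1150
        )
        with pytest.raises(ValueError):
            annotate.classify_nmd(m)


class TestAsEvents:
    def test_skipped_exon(self):
        a = make_transcript("a", [(100, 200), (300, 400), (500, 600)])
        b = make_transcript("b", [(100, 200), (500, 600)])
        (ev,) = annotate.classify_as_events([a, b])
        assert ev.event_type == "SE"
        assert (ev.region_start, ev.region_end) == (300, 400)

    def test_retained_intron(self):
        a = make_transcript("a", [(100, 400)], gene="g")
        b = make_transcript("b", [(100, 200), (300, 400)], gene="g")
        (ev,) = annotate.classify_as_events([a, b])
        assert ev.event_type == "RI"
        assert (ev.region_start, ev.region_end) == (201, 299)

    def test_alternative_donor_plus_strand_is_a5(self):
        a = make_transcript("a", [(100, 200), (300, 400)])
        b = make_transcript("b", [(100, 220), (300, 400)])
        (ev,) = annotate.classify_as_events([a, b])
        assert ev.event_type == "A5"

    def test_alternative_acceptor_plus_strand_is_a3(self):
        a = make_transcript("a", [(100, 200), (300, 400)])
        b = make_transcript("b", [(100, 200), (320, 400)])
        (ev,) = annotate.classify_as_events([a, b])
        assert ev.event_type == "A3"

    def test_shared_acceptor_minus_strand_is_a3(self):
        # on minus strand the donor side is the high-coordinate intron end
        a = make_transcript("a", [(100, 200), (300, 400)], strand="-")
        b = make_transcript("b", [(100, 220), (300, 400)], strand="-")
        (ev,) = annotate.classify_as_events([a, b])
        assert ev.event_type == "A3"

    def test_mutually_exclusive_exons(self):
        a = make_transcript("a", [(100, 200), (300, 350), (500, 600)])
        b = make_transcript("b", [(100, 200), (400, 450), (500, 600)])
        (ev,) = annotate.classify_as_events([a, b])
        assert ev.event_type == "MX"

    def test_alternative_first_exon(self):
        a = make_transcript("a", [(100, 150), (300, 400), (500, 600)])
        b = make_transcript("b", [(210, 260), (300, 400), (500, 600)])
        evs = annotate.classify_as_events([a, b])
        assert [e.event_type for e in evs] == ["AF"]

    def test_symmetry_in_pair_order(self):
        a = make_transcript("a", [(100, 200), (300, 400), (500, 600)])
        b = make_transcript("b", [(100, 200), (500, 600)])
        e1 = annotate.classify_as_events([a, b])
        e2 = annotate.classify_as_events([b, a])
        assert [x.key() for x in e1] == [x.key() for x in e2]


class TestSjsWindows:
    def test_two_bp_windows(self, two_exon_plus):
        wins = annotate.sjs_windows([two_exon_plus])
        assert {(w.start, w.end) for w in wins} == {(201, 202), (298, 299)}

    def test_shared_intron_counted_once(self, two_exon_plus):
        other = make_transcript("t2", [(50, 200), (300, 450)])
        wins = annotate.sjs_windows([two_exon_plus, other])
        assert len(wins) == 2

    def test_single_exon_gene_empty(self):
        assert annotate.sjs_windows([make_transcript("s", [(100, 400)])]) == []


@settings(max_examples=30, deadline=None)
@given(st_h.integers(2, 6), st_h.integers(0, 3))
def test_nnc_calls_always_have_witness(n_exons, shift_idx):
    """Every NNC call exhibits a splice-site coordinate absent from the
    reference site sets."""
    exons = [(100 + 300 * k, 200 + 300 * k) for k in range(n_exons)]
    ref = make_transcript("r", exons)
    shifted = list(exons)
    k = min(shift_idx, n_exons - 2)
    shifted[k] = (exons[k][0], exons[k][1] + 7)
    cand = make_transcript("c", shifted)
    cat = annotate.classify_structure(cand, [ref])
    if cat == "NNC":
        assert annotate.nnc_witness(cand, [ref]) is not None
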