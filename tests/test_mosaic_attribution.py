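"""Parent-of-origin attribution: per-site rule, gene summaries, segments."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from sipmosaic import mosaic_attribution as ma
from sipmosaic.mosaic_attribution import (
    GeneCall,
    SiteLabel,
    attribute_from_projections,
    attribute_sites,
    detect_segments,
    summarize_gene,
)
from sipmosaic.pairalign import QueryProjection
from sipmosaic.seqio import GeneInterval, NucSequence

from .oracles import rule_labels

dna = st.text(alphabet="ACGT", min_size=4, max_size=40)


def track_from_strings(query, pa, pb):
    return attribute_from_projections(
        "q", query, QueryProjection(pa, 0), QueryProjection(pb, 0)
    )


class TestAttributeSites:
    def test_forced_example(self):
        tr = attribute_sites(
            NucSequence("q", "ACGT"), NucSequence("a", "ACGA"), NucSequence("b", "TCGT")
        )
        assert [l.value for l in tr.labels()] == [
            "A_SPECIFIC", "SHARED", "SHARED", "B_SPECIFIC",
        ]

    def test_query_equals_both_parents_all_shared(self):
        tr = attribute_sites(
            NucSequence("q", "ACGTACGT"),
            NucSequence("a", "ACGTACGT"),
            NucSequence("b", "ACGTACGT"),
        )
        assert all(l is SiteLabel.SHARED for l in tr.labels())

    def test_private_mutation_is_novel(self):
        tr = track_from_strings("ACGT", "ACAT", "ACAT")
        assert tr.labels()[2] is SiteLabel.NOVEL

    def test_parent_gap_does_not_match(self):
        tr = track_from_strings("ACGT", "AC-T", "ACGT")
        assert tr.labels()[2] is SiteLabel.B_SPECIFIC

    @given(dna, dna, dna)
    def test_matches_rule_oracle_and_antisymmetry(self, q, a, b):
        tr = attribute_sites(NucSequence("q", q), NucSequence("a", a), NucSequence("b", b))
        expected = rule_labels(q, tr.projection_a.symbols, tr.projection_b.symbols)
        assert [l.value for l in tr.labels()] == expected
        swapped = attribute_sites(NucSequence("q", q), NucSequence("b", b), NucSequence("a", a))
        remap = {"A_SPECIFIC": "B_SPECIFIC", "B_SPECIFIC": "A_SPECIFIC",
                 "SHARED": "SHARED", "NOVEL": "NOVEL"}
        assert [remap[l.value] for l in swapped.labels()] == [l.value for l in tr.labels()]

    @given(dna, dna, dna)
    def test_label_counts_conserve_length(self, q, a, b):
        tr = attribute_sites(NucSequence("q", q), NucSequence("a", a), NucSequence("b", b))
        assert sum(tr.counts().values()) == len(q)


class TestSummarizeGene:
    def test_all_shared_gene_uninformative(self):
        tr = track_from_strings("ACGTACGT", "ACGTACGT", "ACGTACGT")
        rep = summarize_gene(tr, GeneInterval("g", 0, 8))
        assert rep.identity_to_a == rep.identity_to_b == 100.0
        assert rep.gene_call is GeneCall.UNINFORMATIVE

    def test_constructed_partition_counts(self, rng):
        """A gene built with known label counts must report exactly those
        percentages (direct count oracle)."""
        # query of 100 positions: 80 A-specific, 10 shared, 5 B-specific, 5 novel
        q, a, b = [], [], []
        blocks = [("A", 80), ("S", 10), ("B", 5), ("N", 5)]
        for kind, n in blocks:
            for _ in range(n):
                if kind == "A":
                    q.append("A"); a.append("A"); b.append("C")
                elif kind == "S":
                    q.append("G"); a.append("G"); b.append("G")
                elif kind == "B":
                    q.append("T"); a.append("C"); b.append("T")
                else:
                    q.append("C"); a.append("G"); b.append("T")
        tr = track_from_strings("".join(q), "".join(a), "".join(b))
        rep = summarize_gene(tr, GeneInterval("g", 0, 100))
        assert (rep.pct_a_specific, rep.pct_b_specific, rep.pct_shared, rep.pct_novel) == (
            80.0, 5.0, 10.0, 5.0,
        )
        assert rep.identity_to_a == pytest.approx(90.0)
        assert rep.identity_to_b == pytest.approx(15.0)
        # 5 B-specific sites in one run >= min_run on both donors -> mosaic
        # takes precedence here; scattered B sites would give A_LIKE
        assert rep.gene_call is GeneCall.MOSAIC

    def test_scattered_minor_donor_sites_give_a_like(self):
        # B-specific sites isolated between A-specific sites: no B run
        q = "A" * 10
        a = "A" * 10
        b = "ACCA" + "C" * 6  # positions 0,3 shared-with-B? no: b matches q at 0 and 3
        tr = track_from_strings(q, a, b)
        rep = summarize_gene(tr, GeneInterval("g", 0, 10), call_margin=2.0)
        assert rep.gene_call is GeneCall.A_LIKE

    def test_partition_sums_to_100(self, small_parents, small_mosaic):
        pa, pb = small_parents
        mosaic, _truth, _plan = small_mosaic
        tr = attribute_sites(mosaic, pa, pb)
        for g in mosaic.genes:
            rep = summarize_gene(tr, g)
            total = rep.pct_a_specific + rep.pct_b_specific + rep.pct_shared + rep.pct_novel
            assert total == pytest.approx(100.0, abs=0.01)

    def test_out_of_range_gene_rejected(self):
        tr = track_from_strings("ACGT", "ACGT", "ACGT")
        with pytest.raises(ValueError):
            summarize_gene(tr, GeneInterval("g", 0, 10))

    def test_novel_call(self):
        q = "C" * 50
        a = "G" * 50
        b = "T" * 50
        tr = track_from_strings(q, a, b)
        rep = summarize_gene(tr, GeneInterval("g", 0, 50))
        assert rep.pct_novel == 100.0
        assert rep.gene_call is GeneCall.NOVEL


class TestDetectSegments:
    def test_all_one_donor_single_segment(self):
        tr = track_from_strings("AAAA", "AAAA", "CCCC")
        segs, bps = detect_segments(tr, min_run=3)
        assert len(segs) == 1 and segs[0].donor == "A"
        assert bps == []

    def test_two_segments_one_breakpoint(self):
        # 4 A-informative then 4 B-informative sites
        q = "AAAATTTT"
        a = "AAAACCCC"
        b = "GGGGTTTT"
        segs, bps = detect_segments(track_from_strings(q, a, b), min_run=3)
        assert [s.donor for s in segs] == ["A", "B"]
        assert len(bps) == 1
        assert bps[0].start == 4 and bps[0].end == 5

    def test_short_run_absorbed(self):
        # A x4, B x2 (short), A x4 -> single A segment
        q = "AAAA" + "TT" + "AAAA"
        a = "AAAA" + "CC" + "AAAA"
        b = "GGGG" + "TT" + "GGGG"
        segs, bps = detect_segments(track_from_strings(q, a, b), min_run=3)
        assert [s.donor for s in segs] == ["A"]
        assert bps == []

    def test_no_informative_sites(self):
        tr = track_from_strings("ACGT", "ACGT", "ACGT")
        assert detect_segments(tr) == ([], [])

    def test_query_equal_parent_a_one_segment(self):
        q = a = "ACGTACGTACGT"
        b = "ACGTAATTACGT"
        tr = track_from_strings(q, a, b)
        labels = set(tr.labels())
        assert SiteLabel.B_SPECIFIC not in labels and SiteLabel.NOVEL not in labels
        segs, _ = detect_segments(tr)
        assert len(segs) <= 1 and all(s.donor == "A" for s in segs)

    def test_simulated_mosaic_breakpoints_recovered(self, small_parents, small_mosaic):
        pa, pb = small_parents
        mosaic, _truth, plan = small_mosaic
        tr = attribute_sites(mosaic, pa, pb)
        segs, bps = detect_segments(tr, min_run=3)
        true_bps = plan.true_breakpoints()
        assert len(bps) == len(true_bps)
        for t in true_bps:
            assert any(b.start <= t < b.end for b in bps)


class TestExports:
    def test_bed_runs_cover_track(self):
        tr = track_from_strings("AAAATTTT", "AAAACCCC", "GGGGTTTT")
        bed = ma.track_to_bed(tr)
        lines = [l.split("\t") for l in bed.strip().split("\n")]
        assert int(lines[0][1]) == 0 and int(lines[-1][2]) == 8
        covered = sum(int(e) - int(s) for _, s, e, _ in lines)
        assert covered == 8

    def test_gene_tsv_has_fig_columns(self, small_parents, small_mosaic):
        pa, pb = small_parents
        mosaic, _t, _p = small_mosaic
        tr = attribute_sites(mosaic, pa, pb)
        reports = [summarize_gene(tr, g) for g in mosaic.genes]
        tsv = ma.gene_reports_to_tsv(reports)
        header = tsv.splitlines()[0].split("\t")
        assert header[:4] == ["gene", "pct_A_specific", "pct_B_specific", "pct_shared"]
        assert len(tsv.strip().splitlines()) == len(mosaic.genes) + 1

    def test_segment_tsv_one_based(self):
        tr = track_from_strings("AAAATTTT", "AAAACCCC", "GGGGTTTT")
        segs, bps = detect_segments(tr, min_run=3)
        tsv = ma.segments_to_tsv(segs, bps)
        first_seg = tsv.splitlines()[1].split("\t")
        assert first_seg[2] == "1"  # 0-based 0 -> 1-based 1
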