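"""Generator correctness: divergence, mosaic truth, read and pool models."""

import numpy as np
import pytest

from sipmosaic import mosaic_attribution as ma
from sipmosaic import synthetic_community as synth
from sipmosaic.mosaic_attribution import SiteLabel
from sipmosaic.seqio import NucSequence

LAYOUT = synth.scaled_gene_layout(0.1)  # ~1 kb operons for speed


class TestParentPair:
    def test_zero_divergence_identical(self):
        pa, pb = synth.generate_parent_pair(LAYOUT, 0.0, seed=1)
        assert pa.sequence.seq == pb.sequence.seq

    def test_divergence_within_binomial_band(self):
        pa, pb = synth.generate_parent_pair(synth.DEFAULT_GENE_LAYOUT, 0.1, seed=2)
        n = len(pa)
        d = sum(x != y for x, y in zip(pa.sequence.seq, pb.sequence.seq))
        sigma = np.sqrt(n * 0.1 * 0.9)
        assert abs(d - 0.1 * n) <= 3 * sigma

    def test_seed_reproducibility(self):
        a1 = synth.generate_parent_pair(LAYOUT, 0.1, seed=3)
        a2 = synth.generate_parent_pair(LAYOUT, 0.1, seed=3)
        assert a1[0].sequence.seq == a2[0].sequence.seq
        assert a1[1].sequence.seq == a2[1].sequence.seq
        b = synth.generate_parent_pair(LAYOUT, 0.1, seed=4)
        assert b[0].sequence.seq != a1[0].sequence.seq

    def test_per_gene_divergence_mapping(self):
        div = {name: (0.0 if name != "nagD" else 0.2) for name, _ in LAYOUT}
        pa, pb = synth.generate_parent_pair(LAYOUT, div, seed=5)
        g = pa.gene("nagD")
        outside = [
            (x, y)
            for i, (x, y) in enumerate(zip(pa.sequence.seq, pb.sequence.seq))
            if not (g.start <= i < g.end)
        ]
        assert all(x == y for x, y in outside)
        inside_diffs = sum(
            x != y for x, y in zip(pa.sequence.seq[g.start:g.end], pb.sequence.seq[g.start:g.end])
        )
        assert inside_diffs > 0

    def test_invalid_divergence_rejected(self):
        with pytest.raises(ValueError):
            synth.generate_parent_pair(LAYOUT, 0.5, seed=6)


class TestMosaic:
    def test_single_segment_copies_parent_a(self):
        pa, pb = synth.generate_parent_pair(LAYOUT, 0.1, seed=7)
        plan = synth.MosaicPlan((("A", len(pa)),), novel_rate=0.0, seed=8)
        mosaic, truth = synth.generate_mosaic((pa, pb), plan)
        assert mosaic.sequence.seq == pa.sequence.seq
        assert truth.novel_sites == ()

    def test_attribution_closes_the_loop(self, small_parents, small_mosaic):
        """Where the parents differ, the attribution labels must equal the
        planned donors; every novel site must be labelled NOVEL."""
        pa, pb = small_parents
        mosaic, truth, _plan = small_mosaic
        track = ma.attribute_sites(mosaic, pa, pb)
        labels = track.labels()
        novel = set(truth.novel_sites)
        for i, (x, y) in enumerate(zip(pa.sequence.seq, pb.sequence.seq)):
            if i in novel:
                assert labels[i] is SiteLabel.NOVEL
            elif x != y:
                expected = SiteLabel.A_SPECIFIC if truth.donors[i] == "A" else SiteLabel.B_SPECIFIC
                assert labels[i] is expected
            else:
                assert labels[i] is SiteLabel.SHARED

    def test_novel_count_within_binomial_band(self):
        pa, pb = synth.generate_parent_pair(synth.DEFAULT_GENE_LAYOUT, 0.1, seed=9)
        n = len(pa)
        plan = synth.MosaicPlan((("A", n),), novel_rate=0.01, seed=10)
        _m, truth = synth.generate_mosaic((pa, pb), plan)
        sigma = np.sqrt(n * 0.01 * 0.99)
        assert abs(len(truth.novel_sites) - 0.01 * n) <= 3 * sigma

    def test_plan_length_mismatch_rejected(self):
        pa, pb = synth.generate_parent_pair(LAYOUT, 0.1, seed=11)
        with pytest.raises(ValueError):
            synth.generate_mosaic((pa, pb), synth.MosaicPlan((("A", 10),), 0.0, 12))

    def test_truth_json_round_trip(self, small_mosaic):
        import json

        _m, truth, plan = small_mosaic
        data = json.loads(truth.to_json())
        assert data["donors"] == truth.donors
        assert [tuple(s) for s in data["segments"]] == list(plan.segments)


@pytest.fixture(scope="module")
def variants():
    return synth.diverged_variants(["x", "y"], length=1200, divergence=0.05, seed=13)


class TestReads:
    def test_zero_reads(self, variants):
        reads, origins = synth.simulate_reads(variants, [0.5, 0.5], 0, seed=14)
        assert reads == [] and origins == []

    def test_error_free_reads_are_substrings(self, variants):
        reads, origins = synth.simulate_reads(
            variants, [0.5, 0.5], 50, sub_rate=0.0, indel_rate=0.0, seed=15
        )
        by_id = {v.id: v.seq for v in variants}
        from sipmosaic.seqio import revcomp

        for r, o in zip(reads, origins):
            window = by_id[o.variant][o.start:o.end]
            assert r.seq == (window if o.strand == "+" else revcomp(window))

    def test_lengths_within_model(self, variants):
        lm = synth.ReadLengthModel(30, 200)
        reads, _ = synth.simulate_reads(variants, [1.0, 0.0], 100, lm, seed=16)
        assert all(30 <= len(r) <= 200 for r in reads)

    def test_multinomial_band(self, variants):
        w = [0.7, 0.3]
        _reads, origins = synth.simulate_reads(variants, w, 2000, seed=17)
        n_x = sum(o.variant == "x" for o in origins)
        sigma = np.sqrt(2000 * 0.7 * 0.3)
        assert abs(n_x - 1400) <= 3 * sigma

    def test_seed_reproducibility(self, variants):
        r1, _ = synth.simulate_reads(variants, [0.5, 0.5], 20, seed=18)
        r2, _ = synth.simulate_reads(variants, [0.5, 0.5], 20, seed=18)
        assert [(r.id, r.seq) for r in r1] == [(r.id, r.seq) for r in r2]

    def test_informative_windows_differ_from_other_variants(self, variants):
        reads, origins = synth.simulate_reads(
            variants, [0.5, 0.5], 60, sub_rate=0.0, indel_rate=0.0,
            seed=19, min_informative=3,
        )
        seqs = {v.id: v.seq for v in variants}
        for o in origins:
            other = [l for l in seqs if l != o.variant][0]
            diffs = sum(
                a != b
                for a, b in zip(seqs[o.variant][o.start:o.end], seqs[other][o.start:o.end])
            )
            assert diffs >= 3

    def test_bad_weights_rejected(self, variants):
        with pytest.raises(ValueError):
            synth.simulate_reads(variants, [0.5, 0.6], 10, seed=20)


class TestSipPools:
    def test_leakage_zero_single_labelled_taxon(self):
        taxa = (
            synth.TaxonSpec("Degrader", 0.2, True),
            synth.TaxonSpec("Other", 0.8, False),
        )
        panel = synth.make_16s_panel(["Degrader", "Other"], seed=21)
        heavy, _light, truth = synth.simulate_sip_pools(taxa, panel, 100, leakage=0.0, seed=22)
        assert set(truth.heavy_origin.values()) == {"Degrader"}
        assert len(heavy) == 100

    def test_no_labelled_taxon_rejected(self):
        taxa = (synth.TaxonSpec("Other", 1.0, False),)
        panel = synth.make_16s_panel(["Other"], seed=23)
        with pytest.raises(ValueError):
            synth.simulate_sip_pools(taxa, panel, 10, seed=24)

    def test_leakage_bound_rejected(self):
        taxa = (synth.TaxonSpec("D", 1.0, True),)
        panel = synth.make_16s_panel(["D"], seed=25)
        with pytest.raises(ValueError):
            synth.simulate_sip_pools(taxa, panel, 10, leakage=1.0, seed=26)

    def test_true_heavy_fractions_sum_to_one(self):
        taxa = synth.default_sip_community()
        panel = synth.make_16s_panel([t.name for t in taxa], seed=27)
        _h, _l, truth = synth.simulate_sip_pools(taxa, panel, 50, seed=28)
        assert sum(truth.true_heavy_fractions().values()) == pytest.approx(1.0)

    def test_heavy_composition_near_truth(self):
        taxa = synth.default_sip_community()
        panel = synth.make_16s_panel([t.name for t in taxa], seed=29)
        _h, _l, truth = synth.simulate_sip_pools(taxa, panel, 2000, seed=30)
        expected = truth.true_heavy_fractions()
        counts = {}
        for taxon in truth.heavy_origin.values():
            counts[taxon] = counts.get(taxon, 0) + 1
        for name, p in expected.items():
            sigma = np.sqrt(2000 * p * (1 - p))
            assert abs(counts.get(name, 0) - 2000 * p) <= 3 * sigma + 1e-9, name


class TestSyntheticTemplates:
    def test_nagfcqed_template_reproducible(self):
        t1 = synth.synthetic_nagfcqed_record(seed=31)
        t2 = synth.synthetic_nagfcqed_record(seed=31)
        assert t1.seq == t2.seq

    def test_ndo_genome_amplicon_location(self):
        genome, (start, end) = synth.synthetic_ndo_genome(seed=32)
        from sipmosaic import primers
        from sipmosaic.seqio import revcomp

        assert genome.seq[start : start + len(primers.COM1.fwd)] == primers.COM1.fwd
        assert genome.seq[end - len(primers.COM1.rev) : end] == revcomp(primers.COM1.rev)
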