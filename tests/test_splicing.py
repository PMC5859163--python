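"""Gene models, coverage rules, consensus IR/ES calling, splice sites."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phaeotools import simulate as sim
from phaeotools import splicing as sp


def track(depth_by_pos, length=1000, chrom="chr1", sample="s0"):
    arr = np.zeros(length)
    for (a, b), v in depth_by_pos.items():
        arr[a:b] = v
    return sp.CoverageTrack(sample, {chrom: arr})


class TestGeneModel:
    def test_introns_are_exon_gaps(self):
        m = sp.GeneModel("g", "chr1", "+", ((0, 100), (150, 250), (320, 400)))
        assert m.introns == ((100, 150), (250, 320))
        assert m.internal_exons == ((150, 250),)

    def test_overlapping_exons_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            sp.GeneModel("g", "chr1", "+", ((0, 100), (50, 200)))

    def test_bad_strand_rejected(self):
        with pytest.raises(ValueError, match="strand"):
            sp.GeneModel("g", "chr1", ".", ((0, 100),))


class TestEligibility:
    def test_single_exon_gene_excluded(self):
        models = [sp.GeneModel("g", "chr1", "+", ((0, 100),))]
        assert sp.eligible_genes(models) == []

    def test_short_intron_not_ir_analysable(self):
        m = sp.GeneModel("g", "chr1", "+", ((0, 100), (149, 250)))  # 49 bp intron
        [(model, qualifying)] = sp.eligible_genes([m])
        assert model is m
        assert qualifying == ()
        m2 = sp.GeneModel("g2", "chr1", "+", ((0, 100), (150, 250)))  # 50 bp
        [(_, qualifying2)] = sp.eligible_genes([m2])
        assert qualifying2 == ((100, 150),)

    def test_matches_bruteforce_filter(self, rng):
        cfg = sp.ASConfig()
        models = []
        for i in range(40):
            n_ex = int(rng.integers(1, 5))
            pos, exons = 0, []
            for _ in range(n_ex):
                exons.append((pos, pos + int(rng.integers(20, 120))))
                pos = exons[-1][1] + int(rng.integers(20, 90))
            models.append(sp.GeneModel(f"g{i}", "chr1", "+", tuple(exons)))
        got = {m.gene_id: q for m, q in sp.eligible_genes(models, cfg)}
        for m in models:
            if len(m.exons) < 2:
                assert m.gene_id not in got
            else:
                assert got[m.gene_id] == tuple(
                    iv for iv in m.introns if iv[1] - iv[0] >= 50
                )


class TestSpliceSiteClass:
    GENOME = {"chr1": "AAAA" + "GT" + "A" * 60 + "AG" + "TTTT"
                       + "CT" + "C" * 60 + "AC" + "GGGG"}

    def test_plus_strand_canonical(self):
        assert sp.splice_site_class((4, 68), "+", self.GENOME, "chr1") == "canonical"

    def test_minus_strand_canonical(self):
        assert sp.splice_site_class((72, 136), "-", self.GENOME, "chr1") == "canonical"

    def test_gc_donor_non_canonical(self):
        genome = {"chr1": "AA" + "GC" + "A" * 60 + "AG" + "TT"}
        assert sp.splice_site_class((2, 66), "+", genome, "chr1") == "non_canonical"

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            sp.splice_site_class((100, 500), "+", self.GENOME, "chr1")

    def test_strand_symmetry_under_reverse_complement(self, rng):
        """A - strand intron classifies like its reverse-complemented + twin."""
        comp = str.maketrans("ACGT", "TGCA")
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGT"), size=80))
            plus = {"chr1": seq}
            minus = {"chr1": seq.translate(comp)[::-1]}
            iv = (10, 70)
            mirrored = (len(seq) - iv[1], len(seq) - iv[0])
            assert sp.splice_site_class(iv, "+", plus, "chr1") == \
                sp.splice_site_class(mirrored, "-", minus, "chr1")


class TestFeaturePasses:
    def test_85_of_100_at_depth_5_passes(self):
        t = track({(0, 85): 5})
        assert sp.feature_passes((0, 100), t, sp.ASConfig(), "chr1") is True

    def test_80_of_100_fails_boundary(self):
        t = track({(0, 80): 5})
        assert sp.feature_passes((0, 100), t, sp.ASConfig(), "chr1") is False

    def test_depth_exactly_4_does_not_count(self):
        t = track({(0, 100): 4})
        assert sp.feature_passes((0, 100), t, sp.ASConfig(), "chr1") is False

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            sp.feature_passes((10, 10), track({}), sp.ASConfig(), "chr1")

    def test_matches_per_base_counting_oracle(self, rng):
        cfg = sp.ASConfig()
        for _ in range(30):
            arr = rng.poisson(5, size=200).astype(float)
            t = sp.CoverageTrack("s", {"chr1": arr})
            a = int(rng.integers(0, 150))
            b = a + int(rng.integers(1, 50))
            expected = sum(1 for d in arr[a:b] if d > 4) / (b - a) > 0.8
            assert sp.feature_passes((a, b), t, cfg, "chr1") == expected

    @settings(max_examples=40, deadline=None)
    @given(st.floats(min_value=0.5, max_value=0.95),
           st.floats(min_value=1.0, max_value=10.0))
    def test_raising_thresholds_never_converts_fail_to_pass(self, frac, depth):
        cfg = sp.ASConfig()
        arr = np.tile([6.0, 6.0, 3.0, 8.0, 0.0], 20)
        t = sp.CoverageTrack("s", {"chr1": arr})
        base = sp.feature_passes((0, 100), t, cfg, "chr1")
        stricter = sp.ASConfig(horizontal_frac=max(cfg.horizontal_frac, frac),
                               vertical_depth=max(cfg.vertical_depth, depth))
        if sp.feature_passes((0, 100), t, stricter, "chr1"):
            assert base


class TestPerSampleAndConsensus:
    def gene(self):
        return sp.GeneModel("g", "chr1", "+",
                            ((0, 100), (160, 260), (320, 420)))

    def test_unexpressed_gene_emits_no_flags(self):
        expressed, retained, included = sp.per_sample_calls(
            self.gene(), self.gene().introns, track({}), sp.ASConfig()
        )
        assert (expressed, retained, included) == (False, None, None)

    def test_expressed_gene_with_retained_intron(self):
        t = track({(0, 100): 20, (160, 260): 20, (320, 420): 20, (100, 160): 20})
        expressed, retained, included = sp.per_sample_calls(
            self.gene(), self.gene().introns, t, sp.ASConfig()
        )
        assert expressed
        assert retained == (True, False)
        assert included == (True,)

    def test_consensus_rules(self):
        g = self.gene()
        cfg = sp.ASConfig()

        def fake_samples(n, n_retained, n_included):
            out = []
            for i in range(n):
                out.append((True, (i < n_retained, False), (i < n_included,)))
            return out

        # intron retained in 3/10 informative samples -> IR (0.3 > 0.2)
        events = sp.consensus_calls(g, g.introns, fake_samples(10, 3, 10), cfg)
        assert [(e.kind, e.sample_fraction) for e in events] == [("IR", 0.3)]
        # exon included 9/10 -> no ES; 5/10 -> ES
        assert sp.consensus_calls(g, g.introns, fake_samples(10, 0, 9), cfg) == []
        events = sp.consensus_calls(g, g.introns, fake_samples(10, 0, 5), cfg)
        assert [(e.kind, e.sample_fraction) for e in events] == [("ES", 0.5)]

    def test_zero_informative_samples_warns_and_skips(self):
        g = self.gene()
        with pytest.warns(UserWarning, match="no sample"):
            events = sp.consensus_calls(g, g.introns, [(False, None, None)] * 3)
        assert events == []


class TestPlantedTruthRecovery:
    def test_noise_free_event_list_equals_truth(self):
        cfg = sim.SimConfig(seed=11, n_genes=30)
        models, _genome, tracks, truth = sim.simulate_coverage(cfg, noise=False)
        events = sp.call_events(models, tracks)
        called = {(e.gene_id, e.kind, e.feature[1], e.feature[2]) for e in events}
        planted = {(r.gene_id, r.kind, r.start, r.end) for r in truth.itertuples()}
        assert called == planted
        # consensus fractions agree with construction
        frac = {(e.gene_id, e.feature[1]): e.sample_fraction for e in events
                if e.kind == "IR"}
        for r in truth.itertuples():
            if r.kind == "IR":
                assert frac[(r.gene_id, r.start)] == pytest.approx(r.fraction)


class TestReaders:
    def test_written_files_reload_to_same_objects(self, tmp_path):
        cfg = sim.SimConfig(seed=5, n_genes=8, n_samples=3)
        models, genome, tracks, _truth = sim.simulate_coverage(cfg, noise=True)
        sim.write_coverage(models, genome, tracks, tmp_path)
        reloaded = sp.read_gff3(tmp_path / "models.gff3")
        assert [(m.gene_id, m.strand, m.exons) for m in reloaded] == [
            (m.gene_id, m.strand, m.exons) for m in models
        ]
        sizes = {c: len(s) for c, s in genome.items()}
        for t in tracks:
            t2 = sp.read_bedgraph(tmp_path / f"{t.sample_id}.bedgraph",
                                  t.sample_id, sizes)
            np.testing.assert_array_equal(t2.depths["chr1"], t.depths["chr1"])


class TestExpressionContrast:
    def test_identical_distributions(self):
        import pandas as pd

        expr = pd.DataFrame({"WT": [1.0, 2, 3, 4], "T15": [1.0, 2, 3, 4]},
                            index=list("abcd"))
        [row] = sp.expression_contrast({"IR@T15": (list("abcd"), "T15")}, expr, "WT")
        assert row["t"] == 0.0
        assert row["p"] == 1.0

    def test_singleton_set_is_na(self):
        import pandas as pd

        expr = pd.DataFrame({"WT": [1.0], "T15": [9.0]}, index=["a"])
        [row] = sp.expression_contrast({"IR@T15": (["a"], "T15")}, expr, "WT")
        assert np.isnan(row["t"]) and np.isnan(row["p"])

    def test_upshifted_set_detected_in_most_replicates(self):
        """Lognormal x2 shift, n=200/side: Welch p < 0.05 nearly always."""
        import pandas as pd

        detected = 0
        n_rep = 40
        for rep in range(n_rep):
            rng = np.random.default_rng(1000 + rep)
            base = rng.lognormal(mean=0.0, sigma=1.0, size=200)
            shifted = rng.lognormal(mean=0.0, sigma=1.0, size=200) * 2.0
            expr = pd.DataFrame({"WT": base, "T15": shifted},
                                index=[f"g{i}" for i in range(200)])
            [row] = sp.expression_contrast(
                {"IR@T15": (list(expr.index), "T15")}, expr, "WT"
            )
            if row["p"] < 0.05:
                detected += 1
        assert detected >= 0.95 * n_rep
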