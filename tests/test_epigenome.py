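"""Mark annotation, chromatin states, size factors, Welch test."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from phaeotools import epigenome as epi


class TestWelchTTest:
    def test_identical_samples(self):
        res = epi.welch_t_test([1.0, 2, 3], [1.0, 2, 3])
        assert (res.t, res.p) == (0.0, 1.0)

    def test_matches_scipy_oracle_on_seeded_inputs(self, rng):
        for _ in range(100):
            x = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3),
                           size=rng.integers(4, 40))
            y = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3),
                           size=rng.integers(4, 40))
            res = epi.welch_t_test(x, y)
            ref = stats.ttest_ind(x, y, equal_var=False)
            assert res.t == pytest.approx(ref.statistic, rel=1e-8)
            assert res.df == pytest.approx(ref.df, rel=1e-8)
            assert res.p == pytest.approx(ref.pvalue, rel=1e-8)

    def test_small_fixed_vectors_against_oracle(self):
        x, y = [2.1, 3.3, 1.9, 4.0], [5.0, 4.8, 6.1, 5.5]
        res = epi.welch_t_test(x, y)
        ref = stats.ttest_ind(x, y, equal_var=False)
        assert res.t == pytest.approx(ref.statistic, rel=1e-10)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_undersized_sample_is_na(self):
        res = epi.welch_t_test([1.0], [1.0, 2.0])
        assert np.isnan(res.t) and np.isnan(res.p)

    def test_equal_variance_large_n_approaches_pooled_test(self, rng):
        x = rng.normal(0, 1, size=500)
        y = rng.normal(0.1, 1, size=500)
        welch_p = epi.welch_t_test(x, y).p
        pooled_p = stats.ttest_ind(x, y, equal_var=True).pvalue
        assert welch_p == pytest.approx(pooled_p, rel=1e-3)


def features_of(intervals):
    return [(f"f{i}", "chr1", a, b, "gene") for i, (a, b) in enumerate(intervals)]


class TestAnnotateMarks:
    def test_no_overlap_gives_all_false(self):
        m = epi.annotate_marks(features_of([(0, 100)]),
                               {"CG": [("chr1", 200, 300)]})
        assert not m.loc["f0", "CG"]

    def test_one_bp_boundary_overlap(self):
        m = epi.annotate_marks(features_of([(0, 100)]),
                               {"CG": [("chr1", 99, 150)]})
        assert m.loc["f0", "CG"]
        m2 = epi.annotate_marks(features_of([(0, 100)]),
                                {"CG": [("chr1", 100, 150)]})  # abutting
        assert not m2.loc["f0", "CG"]

    def test_min_overlap_threshold(self):
        m = epi.annotate_marks(features_of([(0, 100)]),
                               {"CG": [("chr1", 95, 150)]}, min_overlap=10)
        assert not m.loc["f0", "CG"]

    def test_malformed_interval_rejected(self):
        with pytest.raises(ValueError):
            epi.annotate_marks(features_of([(0, 100)]), {"CG": [("chr1", 5, 5)]})
        with pytest.raises(ValueError):
            epi.annotate_marks([("f0", "chr1", 10, 10, "gene")], {"CG": []})

    def test_matches_quadratic_overlap_oracle(self, rng):
        feats = []
        pos = 0
        for i in range(50):
            a = pos + int(rng.integers(0, 50))
            b = a + int(rng.integers(10, 200))
            feats.append((f"f{i}", "chr1", a, b, "gene"))
            pos = b
        marks = {
            m: [("chr1", int(a), int(a) + int(l))
                for a, l in zip(rng.integers(0, pos, size=80),
                                rng.integers(5, 300, size=80))]
            for m in epi.MARKS
        }
        got = epi.annotate_marks(feats, marks, min_overlap=1)
        for fid, _c, a, b, _cl in feats:
            for m, ivs in marks.items():
                expected = any(min(b, e) - max(a, s) >= 1 for _c2, s, e in ivs)
                assert got.loc[fid, m] == expected

    def test_state_invariant_to_mark_interval_order(self, rng):
        feats = features_of([(0, 100), (200, 350)])
        ivs = [("chr1", 10, 60), ("chr1", 220, 240), ("chr1", 90, 210)]
        marks = {"CG": ivs, "H3K4me2": list(reversed(ivs))}
        m1 = epi.annotate_marks(feats, marks)
        marks_shuffled = {"CG": list(reversed(ivs)), "H3K4me2": ivs}
        m2 = epi.annotate_marks(feats, marks_shuffled)
        assert m1.apply(epi.chromatin_state, axis=1).equals(
            m2.apply(epi.chromatin_state, axis=1)
        )


class TestChromatinState:
    def test_exhaustive_256_combinations(self):
        for bits in itertools.product([False, True], repeat=8):
            row = dict(zip(epi.MARKS, bits))
            active = any(row[m] for m in epi.ACTIVE_MARKS)
            repressive = any(row[m] for m in epi.REPRESSIVE_MARKS)
            expected = ("BOTH" if active and repressive
                        else "ACTIVE_ONLY" if active
                        else "REPRESSIVE_ONLY" if repressive
                        else "UNMARKED")
            assert epi.chromatin_state(row) == expected

    def test_polarity_table(self):
        assert epi.MARK_POLARITY["H3K4me2"] == "active"
        assert epi.MARK_POLARITY["H3K9_14Ac"] == "active"
        for m in ("CG", "CHG", "CHH", "H3K27me3", "H3K9me2", "H3K9me3"):
            assert epi.MARK_POLARITY[m] == "repressive"


class TestMethylationContext:
    TABLE = {
        (False, False, False): "unmethylated",
        (True, False, False): "CG_only",
        (False, True, False): "CHG_involved",
        (False, False, True): "CHH_only",
        (True, True, False): "CHG_involved",
        (True, False, True): "CG_plus_CHH",
        (False, True, True): "CHG_involved",
        (True, True, True): "CHG_involved",
    }

    def test_all_eight_triples(self):
        for (cg, chg, chh), expected in self.TABLE.items():
            row = {"CG": cg, "CHG": chg, "CHH": chh}
            assert epi.methylation_context_class(row) == expected


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        counts = pd.DataFrame({"a": [10, 20, 5], "b": [10, 20, 5]})
        np.testing.assert_allclose(epi.size_factors(counts), [1.0, 1.0])

    def test_doubled_column_doubles_factor(self):
        counts = pd.DataFrame({"a": [10, 20, 5], "b": [20, 40, 10]})
        sf = epi.size_factors(counts)
        assert sf["b"] / sf["a"] == pytest.approx(2.0)

    def test_matches_independent_median_of_ratios(self, rng):
        counts = pd.DataFrame(rng.integers(1, 500, size=(60, 5)),
                              columns=list("abcde"))
        sf = epi.size_factors(counts)
        mat = counts.to_numpy(float)
        geo = np.exp(np.log(mat).mean(axis=1))
        for j, col in enumerate("abcde"):
            assert sf[col] == pytest.approx(np.median(mat[:, j] / geo), rel=1e-12)

    def test_global_scaling_cancels_but_per_column_scaling_moves(self, rng):
        counts = pd.DataFrame(rng.integers(1, 500, size=(40, 3)),
                              columns=list("abc"))
        sf = epi.size_factors(counts)
        np.testing.assert_allclose(epi.size_factors(counts * 3), sf)
        scaled = counts.copy()
        scaled["c"] = scaled["c"] * 5
        sf2 = epi.size_factors(scaled)
        assert sf2["c"] / sf["c"] == pytest.approx(5 ** (2 / 3), rel=1e-9)

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            epi.size_factors(pd.DataFrame({"a": [0, 0], "b": [0, 0]}))


class TestExpressionQuartiles:
    def test_uniform_values_split_evenly(self):
        q = epi.expression_quartiles(pd.Series(range(1, 9)))
        assert list(q) == ["Q1", "Q1", "Q2", "Q2", "Q3", "Q3", "Q4", "Q4"]

    def test_all_equal_values_are_q1(self):
        q = epi.expression_quartiles(pd.Series([5.0] * 6))
        assert set(q) == {"Q1"}

    def test_matches_sort_and_split_oracle(self, rng):
        values = pd.Series(rng.normal(size=200))
        q = epi.expression_quartiles(values)
        q25, q50, q75 = np.quantile(values, [0.25, 0.5, 0.75])
        for v, label in zip(values, q):
            expected = ("Q1" if v <= q25 else "Q2" if v <= q50
                        else "Q3" if v <= q75 else "Q4")
            assert label == expected

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            epi.expression_quartiles(pd.Series([1.0, 2.0, 3.0]))


def matrix_from_combos(combos):
    rows = []
    for i, combo in enumerate(combos):
        row = {"feature_class": "gene"}
        for m in epi.MARKS:
            row[m] = m in combo
        rows.append(pd.Series(row, name=f"f{i}"))
    return pd.DataFrame(rows)


class TestCompareMarkedVsUnmarked:
    def test_null_combination_not_significant(self, rng):
        combos = [()] * 60 + [("H3K4me2",)] * 60
        matrix = matrix_from_combos(combos)
        expr = pd.Series(rng.lognormal(size=120), index=matrix.index)
        [row] = epi.compare_marked_vs_unmarked(matrix, expr).to_dict("records")
        assert row["combination"] == "H3K4me2"
        assert row["p"] > 0.01  # same distribution: rarely small

    def test_empty_unmarked_set_rejected(self, rng):
        matrix = matrix_from_combos([("CG",)] * 5)
        expr = pd.Series(rng.lognormal(size=5), index=matrix.index)
        with pytest.raises(ValueError):
            epi.compare_marked_vs_unmarked(matrix, expr)

    def test_n_sums_to_marked_features(self, rng):
        combos = ([()] * 30 + [("CG",)] * 20 + [("CG", "H3K27me3")] * 15
                  + [("H3K4me2",)] * 10)
        matrix = matrix_from_combos(combos)
        expr = pd.Series(rng.lognormal(size=len(combos)), index=matrix.index)
        result = epi.compare_marked_vs_unmarked(matrix, expr)
        assert result["n"].sum() == len(combos) - 30

    def test_repressive_effect_detected_in_most_replicates(self):
        detected = 0
        n_rep = 40
        for rep in range(n_rep):
            rng = np.random.default_rng(2000 + rep)
            combos = [()] * 80 + [("CG",)] * 80
            matrix = matrix_from_combos(combos)
            expr = np.concatenate([
                rng.lognormal(mean=np.log(100), sigma=1.0, size=80),
                rng.lognormal(mean=np.log(100), sigma=1.0, size=80) * 0.25,
            ])
            result = epi.compare_marked_vs_unmarked(
                matrix, pd.Series(expr, index=matrix.index)
            )
            row = result.iloc[0]
            if row["p"] < 0.05 and row["t"] < 0:
                detected += 1
        assert detected >= 0.95 * n_rep

    def test_te_class_summary_matches_counting_oracle(self, rng):
        classes = ["TE_classI", "TE_classII", "gene"]
        rows = []
        for i in range(90):
            row = {"feature_class": classes[i % 3]}
            for m in epi.MARKS:
                row[m] = bool(rng.random() < 0.3)
            rows.append(pd.Series(row, name=f"f{i}"))
        matrix = pd.DataFrame(rows)
        table = epi.te_context_summary(matrix)
        for cls in ("TE_classI", "TE_classII"):
            sub = matrix[matrix["feature_class"] == cls]
            for ctx in table.columns:
                expected = sum(
                    epi.methylation_context_class(r) == ctx
                    for _i, r in sub.iterrows()
                )
                got = table.loc[cls, ctx] if cls in table.index else 0
                assert got == expected
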