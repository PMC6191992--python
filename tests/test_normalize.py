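"""Normalization oracles: direct-formula checks and frozen edgeR values."""
import numpy as np
import pandas as pd
import pytest

import canalkit as ck
from canalkit.datatypes import CountMatrix

#: edgeR 4.0.16 calcNormFactors(method="TMM", logratioTrim=0.30, sumTrim=0.05)
#: on the toy_counts fixture, and on the same fixture with sample B scaled 7x
#: (frozen independent oracle values)
EDGER_TMM_TOY = [1.04448019, 0.91928330, 1.02930202, 1.01183010]
EDGER_TMM_TOY_B7 = [1.050710, 0.903029, 1.035441, 1.017865]


def _cm(arr, columns=None, lengths=None):
    arr = np.asarray(arr)
    df = pd.DataFrame(arr, index=[f"g{i}" for i in range(arr.shape[0])],
                      columns=columns or [f"s{j}" for j in range(arr.shape[1])])
    return CountMatrix(df, None if lengths is None else pd.Series(lengths, index=df.index))


class TestLog2Cpm:
    def test_zero_counts_equal_libraries_constant(self):
        cm = _cm(np.zeros((4, 3), int) + [[10], [10], [10], [10]])
        out = ck.log2_cpm(cm).values.to_numpy()
        assert np.allclose(out, out[0, 0])

    def test_invariant_to_depth_rescaling(self):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 500, (30, 3))
        doubled = x.copy()
        doubled[:, 1] *= 2  # library size doubles with the counts
        a = ck.log2_cpm(_cm(x)).values.to_numpy()
        b = ck.log2_cpm(_cm(doubled)).values.to_numpy()
        assert np.allclose(a[:, 1], b[:, 1], atol=1e-12)

    def test_matches_direct_arithmetic_oracle(self):
        counts = np.array([[10, 20], [0, 5], [90, 75]], float)
        cm = _cm(counts.astype(int))
        out = ck.log2_cpm(cm, prior_count=0.5).values.to_numpy()
        lib = counts.sum(axis=0)
        prior = 0.5 * lib / 1e6
        expected = np.log2((counts + prior) / (lib + 2 * prior) * 1e6)
        assert np.allclose(out, expected, atol=1e-12)

    def test_monotone_in_counts(self):
        cm = _cm([[1, 1], [50, 50], [500, 500]])
        out = ck.log2_cpm(cm).values.to_numpy()
        assert (np.diff(out[:, 0]) > 0).all()


class TestLog2Rpkm:
    def test_unit_length_equals_cpm(self):
        cm = _cm([[10, 20], [30, 5]], lengths=[1000, 2000])
        rpkm = ck.log2_rpkm(cm).values
        cpm = ck.log2_cpm(cm).values
        assert np.allclose(rpkm.iloc[0], cpm.iloc[0])
        # doubled length -> exactly one log2 unit lower
        assert np.allclose(rpkm.iloc[1], cpm.iloc[1] - 1.0)

    def test_correlates_with_length_corrected_cpm(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(1, 2000, (300, 4))
        lengths = rng.integers(300, 20000, 300)
        cm = _cm(counts, lengths=lengths)
        rpkm = ck.log2_rpkm(cm).values.to_numpy().ravel()
        alt = (ck.log2_cpm(cm).values.to_numpy()
               - np.log2(lengths / 1000.0)[:, None]).ravel()
        assert np.corrcoef(rpkm, alt)[0, 1] > 0.97

    def test_missing_lengths_raise(self):
        with pytest.raises(ValueError):
            ck.log2_rpkm(_cm([[1, 2]]))


class TestFilterLowExpression:
    def _design(self, n_h=3, n_c=3):
        return ck.generate_design(n_h, n_c, 2, rep_scheme={"human": 0, "chimpanzee": 0}, seed=0)

    def test_all_above_threshold_kept(self):
        d = self._design()
        expr = ck.ExpressionMatrix(pd.DataFrame(
            2.0, index=["a", "b"], columns=d.sample_id))
        kept = ck.filter_low_expression(expr, d, 1.5, {"human": 3, "chimpanzee": 3})
        assert list(kept) == ["a", "b"]

    def test_threshold_is_strict(self):
        d = self._design()
        expr = ck.ExpressionMatrix(pd.DataFrame(
            1.5, index=["a"], columns=d.sample_id))
        kept = ck.filter_low_expression(expr, d, 1.5, {"human": 1, "chimpanzee": 1})
        assert len(kept) == 0

    def test_matches_bruteforce_count_oracle(self):
        d = self._design(4, 4)
        rng = np.random.default_rng(2)
        vals = pd.DataFrame(rng.normal(1.5, 1.0, (100, len(d))),
                            index=[f"g{i}" for i in range(100)], columns=d.sample_id)
        expr = ck.ExpressionMatrix(vals)
        mins = {"human": 2, "chimpanzee": 3}
        kept = set(ck.filter_low_expression(expr, d, 1.5, mins))
        expected = set()
        for g in vals.index:
            ok = True
            for sp, need in mins.items():
                cols = d.loc[d.species == sp, "sample_id"]
                ok &= int((vals.loc[g, cols] > 1.5).sum()) >= need
            if ok:
                expected.add(g)
        assert kept == expected

    def test_monotone_in_threshold(self):
        d = self._design(4, 4)
        rng = np.random.default_rng(3)
        expr = ck.ExpressionMatrix(pd.DataFrame(
            rng.normal(1.5, 1.0, (80, len(d))), columns=d.sample_id))
        mins = {"human": 2, "chimpanzee": 2}
        prev = set(ck.filter_low_expression(expr, d, 0.5, mins))
        for thr in (1.0, 1.5, 2.0):
            cur = set(ck.filter_low_expression(expr, d, thr, mins))
            assert cur <= prev
            prev = cur

    def test_unreachable_minimum_raises(self):
        d = self._design()
        expr = ck.ExpressionMatrix(pd.DataFrame(2.0, index=["a"], columns=d.sample_id))
        with pytest.raises(ValueError):
            ck.filter_low_expression(expr, d, 1.5, {"human": 99, "chimpanzee": 1})


class TestTmm:
    def test_identical_columns_unit_factors(self):
        col = np.arange(1, 41)
        diag = ck.tmm_factors(_cm(np.column_stack([col, col])))
        assert np.allclose(diag.factors, 1.0, atol=1e-12)

    def test_pure_depth_scaling_unit_factors(self):
        col = np.arange(1, 41)
        diag = ck.tmm_factors(_cm(np.column_stack([col, 2 * col])))
        assert np.allclose(diag.factors, 1.0, atol=1e-9)

    def test_matches_frozen_edger_oracle(self, toy_counts):
        diag = ck.tmm_factors(toy_counts)
        assert np.allclose(diag.factors.to_numpy(), EDGER_TMM_TOY, atol=1e-6)

    def test_near_invariance_to_scaling_one_sample(self, toy_counts):
        """Scaling one sample perturbs factors only through the precision
        weights (a ~1% effect); the scaled factors match edgeR exactly."""
        base = ck.tmm_factors(toy_counts).factors.to_numpy()
        scaled = toy_counts.counts.copy()
        scaled["B"] = (scaled["B"] * 7).astype(int)
        got = ck.tmm_factors(CountMatrix(scaled)).factors.to_numpy()
        assert np.allclose(got, EDGER_TMM_TOY_B7, atol=1e-6)
        assert np.allclose(got, base, rtol=0.02)

    def test_exact_invariance_to_global_rescaling(self, toy_counts):
        base = ck.tmm_factors(toy_counts).factors.to_numpy()
        scaled = CountMatrix(toy_counts.counts * 3)
        got = ck.tmm_factors(scaled).factors.to_numpy()
        assert np.allclose(got, base, atol=1e-9)

    def test_inflated_gene_shifts_factor_down(self):
        rng = np.random.default_rng(4)
        x = rng.integers(50, 150, (20, 2))
        x[0, 1] *= 10
        diag = ck.tmm_factors(_cm(x))
        # sample 1 carries the inflated gene; its factor must drop below 1
        assert diag.factors.iloc[1] < 1.0 < diag.factors.iloc[0]

    def test_requires_two_samples(self):
        with pytest.raises(ValueError):
            ck.tmm_factors(_cm([[1], [2]]))


class TestCyclicLoess:
    def test_identical_columns_unchanged(self):
        rng = np.random.default_rng(5)
        col = rng.normal(5, 2, 200)
        expr = ck.ExpressionMatrix(pd.DataFrame({"a": col, "b": col}))
        out = ck.cyclic_loess(expr, iterations=2)
        assert np.allclose(out.values.to_numpy(), expr.values.to_numpy(), atol=1e-9)

    def test_constant_offset_removed(self):
        rng = np.random.default_rng(6)
        base = rng.normal(5, 2, 300)
        expr = ck.ExpressionMatrix(pd.DataFrame({"a": base, "b": base + 0.8}))
        out = ck.cyclic_loess(expr, iterations=1).values
        assert np.abs(out["a"] - out["b"]).max() < 1e-6

    def test_pairwise_A_values_preserved(self):
        rng = np.random.default_rng(7)
        expr = ck.ExpressionMatrix(pd.DataFrame(rng.normal(5, 1, (150, 2)),
                                                columns=["a", "b"]))
        out = ck.cyclic_loess(expr, iterations=1)
        a_before = expr.values.mean(axis=1)
        a_after = out.values.mean(axis=1)
        assert np.allclose(a_before, a_after, atol=1e-10)

    def test_reduces_ma_trends(self):
        rng = np.random.default_rng(8)
        base = rng.normal(6, 1.5, (400, 3))
        base[:, 1] += 0.15 * base[:, 1]  # intensity-dependent distortion
        expr = ck.ExpressionMatrix(pd.DataFrame(base, columns=list("abc")))
        out = ck.cyclic_loess(expr, iterations=3, span=0.7).values.to_numpy()
        def max_trend(v):
            worst = 0.0
            for i in range(3):
                for j in range(i + 1, 3):
                    worst = max(worst, abs((v[:, i] - v[:, j]).mean()))
            return worst
        assert max_trend(out) < max_trend(base)

    def test_single_sample_raises(self):
        with pytest.raises(ValueError):
            ck.cyclic_loess(ck.ExpressionMatrix(pd.DataFrame({"a": [1.0, 2.0]})))


class TestVoomWeights:
    def test_weights_positive_finite_and_track_counts(self):
        # shallow libraries so counting noise actually varies across genes
        d = ck.generate_design(4, 4, 2, rep_scheme={"human": 0, "chimpanzee": 0},
                               seed=9, mean_lib_size=5e5)
        p = ck.SimParams(n_genes=600, ind_sd=0.2, baseline_mean=1.0,
                         baseline_sd=2.0, dispersion=0.05, day_effect_sd=0.5)
        cm, _ = ck.simulate_counts(d, p, seed=10)
        X, _ = ck.build_design_matrix(d)
        out = ck.voom_weights(cm, X)
        w = out.weights.to_numpy()
        assert np.isfinite(w).all() and (w > 0).all()
        from scipy.stats import spearmanr
        rho = spearmanr(cm.counts.to_numpy().mean(axis=1), w.mean(axis=1)).statistic
        assert rho > 0

    def test_homoscedastic_data_gives_flat_weights(self):
        # counts built so every gene sits at the same depth: flat trend
        rng = np.random.default_rng(11)
        base = np.full((500, 8), 1000.0)
        noisy = rng.normal(base, 30).clip(1).astype(int)
        cm = _cm(noisy)
        X = np.column_stack([np.ones(8), np.repeat([0, 1], 4)])
        out = ck.voom_weights(cm, X)
        w = out.weights.to_numpy()
        assert w.std() / w.mean() < 0.2

    def test_rank_deficient_design_raises(self):
        cm = _cm([[10, 20, 30, 40]] * 3)
        X = np.column_stack([np.ones(4), np.ones(4)])
        with pytest.raises(ValueError):
            ck.voom_weights(cm, X)


class TestCombineReplicates:
    def test_identical_replicates_pass_through(self):
        d = ck.generate_design(2, 2, 2, rep_scheme={"human": 1, "chimpanzee": 0}, seed=12)
        rng = np.random.default_rng(13)
        vals = pd.DataFrame(rng.normal(5, 1, (40, len(d))), columns=d.sample_id)
        # make H1's replicate columns identical
        for day in (0, 1):
            a, b = d.loc[(d.individual == "H1") & (d.day == day), "sample_id"]
            vals[b] = vals[a]
        expr = ck.ExpressionMatrix(vals)
        comb, red = ck.combine_replicates(expr, d)
        for day in (0, 1):
            a = d.loc[(d.individual == "H1") & (d.day == day), "sample_id"].iloc[0]
            assert np.allclose(comb.values[f"H1_d{day}"], vals[a])
        # singletons pass through untouched
        h2 = d.loc[(d.individual == "H2") & (d.day == 0), "sample_id"].iloc[0]
        assert np.allclose(comb.values["H2_d0"], vals[h2])
        assert len(red) == 8

    def test_pre_and_post_methods_agree(self, small_study):
        counts, _, design = small_study
        diag = ck.tmm_factors(counts)
        expr = ck.log2_cpm(counts, diag.factors)
        post, _ = ck.combine_replicates(expr, design, "post_average")
        pre, _ = ck.combine_replicates(None, design, "pre_sum", counts=counts, loess=False)
        r = np.corrcoef(post.values.to_numpy().ravel(), pre.values.to_numpy().ravel())[0, 1]
        assert r > 0.99

    def test_pre_sum_without_counts_raises(self, small_study):
        _, _, design = small_study
        with pytest.raises(ValueError):
            ck.combine_replicates(None, design, "pre_sum")


class TestSubsampleDepth:
    def test_anomalous_library_thinned(self):
        rng = np.random.default_rng(14)
        x = rng.integers(50, 150, (100, 4))
        x[:, 2] *= 3
        cm = _cm(x)
        thinned, target = ck.subsample_depth(cm, ratio=1.8, seed=0)
        assert target == "s2"
        libs = thinned.counts.sum(axis=0).sort_values(ascending=False)
        assert libs.iloc[0] / libs.iloc[1] < 1.1

    def test_balanced_libraries_untouched(self, toy_counts):
        out, target = ck.subsample_depth(toy_counts, ratio=1.8, seed=0)
        assert target is None
        pd.testing.assert_frame_equal(out.counts, toy_counts.counts)
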