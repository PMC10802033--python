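import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import pica
from pica.preprocess import DesignMatrix


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_enumeration_oracle(n0, n1, n2):
    """Exact-integer enumeration over all heterozygote counts with the
    observed allele counts; independent of the recurrence implementation."""
    n = n0 + n1 + n2
    rare = min(2 * n0 + n1, 2 * n2 + n1)
    if rare == 0:
        return 1.0
    weights = {}
    for h in range(rare % 2, rare + 1, 2):
        hom_r = (rare - h) // 2
        hom_c = n - h - hom_r
        if hom_c < 0:
            continue
        weights[h] = (math.factorial(n)
                      // (math.factorial(hom_r) * math.factorial(h) * math.factorial(hom_c))
                      * 2 ** h)
    total = sum(weights.values())
    p_obs = weights[n1] / total
    return min(1.0, sum(wt / total for wt in weights.values()
                        if wt / total <= p_obs * (1 + 1e-12)))


class TestHWE:
    def test_monomorphic_is_one(self):
        assert pica.hwe_exact_test(50, 0, 0) == 1.0
        assert pica.hwe_exact_test(0, 0, 50) == 1.0

    @pytest.mark.parametrize("counts", [(10, 10, 10), (5, 20, 35), (1, 1, 1),
                                        (25, 10, 25), (0, 30, 0), (3, 0, 17)])
    def test_matches_enumeration_oracle(self, counts):
        assert pica.hwe_exact_test(*counts) == pytest.approx(
            hwe_enumeration_oracle(*counts), rel=1e-10)

    @given(st.integers(0, 40), st.integers(0, 40), st.integers(0, 40))
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_symmetric_in_homozygote_swap(self, n0, n1, n2):
        if n0 + n1 + n2 == 0:
            return
        assert pica.hwe_exact_test(n0, n1, n2) == pytest.approx(
            pica.hwe_exact_test(n2, n1, n0), rel=1e-12)

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            pica.hwe_exact_test(0, 0, 0)


# ---------------------------------------------------------------------------
# Variant QC
# ---------------------------------------------------------------------------

def _qc_inputs(dosages, labels=None):
    idx = [f"s{i}" for i in range(len(dosages))]
    d = pd.Series(dosages, index=idx, name="v1", dtype=float)
    labels = labels or ["d0"] * len(dosages)
    return d, pd.Series(labels, index=idx)


class TestVariantQC:
    def test_balanced_variant_passes(self):
        d, ds = _qc_inputs([0] * 25 + [1] * 50 + [2] * 25)
        qc = pica.variant_qc(d, ds)
        assert qc.passed and qc.maf == 0.5
        assert qc.genotype_group_counts == (25, 50, 25)

    def test_low_maf_fails_with_reason(self):
        d, ds = _qc_inputs([0] * 92 + [1] * 8)  # MAF = 0.04
        qc = pica.variant_qc(d, ds)
        assert not qc.passed and "maf" in qc.fail_reasons

    def test_hwe_failure_below_default_threshold(self):
        # extreme heterozygote deficit: exact p far below 1e-4
        d, ds = _qc_inputs([0] * 50 + [2] * 50)
        qc = pica.variant_qc(d, ds)
        assert qc.hwe_p < 1e-4 and "hwe" in qc.fail_reasons

    def test_low_call_rate_dataset_is_fully_masked(self):
        dosages = [0] * 25 + [1] * 50 + [2] * 25 + [np.nan] * 2 + [1] * 18
        labels = ["big"] * 100 + ["small"] * 20  # small: call rate 0.9
        d, ds = _qc_inputs(dosages, labels)
        qc = pica.variant_qc(d, ds, thresholds={"min_dataset_size": 1})
        assert qc.masked_datasets == ["small"]
        assert sum(qc.genotype_group_counts) == 100  # small samples excluded

    def test_eqtl_pvalue_filter(self):
        d, ds = _qc_inputs([0] * 25 + [1] * 50 + [2] * 25)
        assert not pica.variant_qc(d, ds, eqtl_pvalue=0.2).passed
        assert pica.variant_qc(d, ds, eqtl_pvalue=0.001).passed

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_allele_flip_invariance(self, seed):
        rng = np.random.default_rng(seed)
        dos = rng.binomial(2, rng.uniform(0.05, 0.5), 120).astype(float)
        d, ds = _qc_inputs(dos)
        d2, _ = _qc_inputs(2.0 - dos)
        a, b = pica.variant_qc(d, ds), pica.variant_qc(d2, ds)
        assert a.passed == b.passed
        assert a.maf == pytest.approx(b.maf)
        assert a.hwe_p == pytest.approx(b.hwe_p)


def test_qc_filter_eqtls_keeps_only_passing(sim_small):
    data, _ = sim_small
    filtered, table = pica.qc_filter_eqtls(data)
    assert len(filtered.eqtls) == int(table["pass"].sum())
    assert set(table.columns) >= {"maf", "hwe_p", "pass"}


# ---------------------------------------------------------------------------
# Standardization
# ---------------------------------------------------------------------------

class TestStandardize:
    def test_matches_independent_step_by_step_pipeline(self, toy_expression):
        out = pica.standardize_expression(toy_expression, pseudocount=1.0,
                                          min_mean_log_expression=None)
        # independent oracle: plain numpy, step by step
        v = np.log2(toy_expression.values.to_numpy() + 1.0)
        v = v - v.mean(axis=1, keepdims=True)
        v = (v - v.mean(axis=0)) / v.std(axis=0)
        np.testing.assert_allclose(out.values.to_numpy(), v, atol=1e-12)
        assert out.state == "standardized"

    def test_sample_columns_have_mean_zero_sd_one(self, toy_expression):
        out = pica.standardize_expression(toy_expression,
                                          min_mean_log_expression=None)
        cols = out.values.to_numpy()
        np.testing.assert_allclose(cols.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(cols.std(axis=0), 1.0, atol=1e-10)

    def test_constant_gene_removed(self):
        df = pd.DataFrame([[1.0, 1.0, 1.0], [8.0, 4.0, 2.0], [2.0, 9.0, 5.0]],
                          index=["flat", "g2", "g3"], columns=list("abc"))
        out = pica.standardize_expression(pica.ExpressionMatrix(df),
                                          min_mean_log_expression=None)
        assert "flat" not in out.values.index

    def test_low_expression_gene_removed(self):
        df = pd.DataFrame([[0.1, 0.2, 0.05], [8.0, 4.0, 2.0], [2.0, 9.0, 5.0]],
                          index=["low", "g2", "g3"], columns=list("abc"))
        out = pica.standardize_expression(pica.ExpressionMatrix(df))
        assert "low" not in out.values.index


# ---------------------------------------------------------------------------
# Design matrix + residualization
# ---------------------------------------------------------------------------

class TestBuildDesign:
    def test_single_dataset_has_no_indicators(self):
        ds = pd.Series(["a"] * 5, index=[f"s{i}" for i in range(5)])
        design = pica.build_design(None, ds)
        assert design.values.shape[1] == 0

    def test_three_datasets_give_two_flagged_indicators(self):
        ds = pd.Series(["a", "a", "b", "b", "c", "c"],
                       index=[f"s{i}" for i in range(6)])
        design = pica.build_design(None, ds)
        assert design.values.shape[1] == 2
        assert design.interaction_flags.all()

    def test_duplicated_covariate_raises_collinearity(self):
        idx = [f"s{i}" for i in range(5)]
        cov = pd.DataFrame({"x": np.arange(5.0), "y": np.arange(5.0)}, index=idx)
        ds = pd.Series(["a"] * 5, index=idx)
        with pytest.raises(ValueError, match="collinear"):
            pica.build_design(cov, ds)


class TestResidualize:
    def _standardized(self, values, columns):
        return pica.ExpressionMatrix(
            pd.DataFrame(values, index=[f"g{i}" for i in range(len(values))],
                         columns=columns), state="standardized")

    def test_intercept_only_centers_each_gene(self, rng):
        cols = [f"s{i}" for i in range(20)]
        expr = self._standardized(rng.normal(size=(3, 20)), cols)
        design = DesignMatrix(pd.DataFrame(index=cols), pd.Series(dtype=bool))
        out = pica.residualize(expr, design)
        np.testing.assert_allclose(out.values.to_numpy().mean(axis=1), 0, atol=1e-12)
        assert out.state == "residualized"

    def test_residuals_orthogonal_to_design(self, rng):
        n = 50
        cols = [f"s{i}" for i in range(n)]
        cov = pd.DataFrame(rng.normal(size=(n, 5)),
                           columns=[f"c{i}" for i in range(5)], index=cols)
        expr = self._standardized(rng.normal(size=(10, n)), cols)
        design = DesignMatrix(cov, pd.Series(False, index=cov.columns))
        out = pica.residualize(expr, design)
        R = out.values.to_numpy()
        dots = np.abs(R @ cov.to_numpy())
        assert dots.max() < 1e-8

    def test_expression_equal_to_covariate_gives_zero_residuals(self, rng):
        n = 30
        cols = [f"s{i}" for i in range(n)]
        x = rng.normal(size=n)
        expr = self._standardized(x[None, :], cols)
        design = DesignMatrix(pd.DataFrame({"x": x}, index=cols),
                              pd.Series({"x": False}))
        out = pica.residualize(expr, design)
        assert np.abs(out.values.to_numpy()).max() < 1e-10

    def test_residualize_is_a_fixed_point(self, rng):
        n = 40
        cols = [f"s{i}" for i in range(n)]
        cov = pd.DataFrame(rng.normal(size=(n, 3)), columns=list("xyz"), index=cols)
        expr = self._standardized(rng.normal(size=(5, n)), cols)
        design = DesignMatrix(cov, pd.Series(False, index=cov.columns))
        once = pica.residualize(expr, design)
        twice = pica.residualize(once, design)
        np.testing.assert_allclose(once.values.to_numpy(),
                                   twice.values.to_numpy(), atol=1e-10)

    def test_missing_genotype_leaves_residual_missing(self, rng):
        n = 30
        cols = [f"s{i}" for i in range(n)]
        g = rng.binomial(2, 0.4, n).astype(float)
        g[0] = np.nan
        expr = self._standardized(rng.normal(size=(1, n)), cols)
        geno = pica.GenotypeMatrix(pd.DataFrame(g[None, :], index=["v1"], columns=cols))
        eqtls = pd.DataFrame({"gene": ["g0"], "variant": ["v1"]})
        cov = pd.DataFrame({"x": rng.normal(size=n)}, index=cols)
        design = DesignMatrix(cov, pd.Series({"x": True}))
        out = pica.residualize(expr, design, geno, eqtls)
        assert np.isnan(out.values.iloc[0, 0])
        assert np.isfinite(out.values.to_numpy()[0, 1:]).all()


# ---------------------------------------------------------------------------
# Force-normal transform
# ---------------------------------------------------------------------------

class TestForceNormal:
    def test_median_maps_to_zero_and_order_is_kept(self):
        out = pica.force_normal([3.0, 1.0, 2.0])
        assert out[2] == pytest.approx(0.0, abs=1e-12)
        assert out[1] < out[2] < out[0]

    def test_ties_get_equal_values(self):
        out = pica.force_normal([1.0, 1.0, 2.0])
        assert out[0] == out[1]

    def test_matches_inverse_cdf_oracle(self, rng):
        x = rng.normal(size=100)
        out = pica.force_normal(x)
        ranks = stats.rankdata(x)
        expected = stats.norm.ppf((ranks - 0.5) / 100)
        np.testing.assert_allclose(out, expected, atol=1e-12)
        assert abs(out.mean()) < 1e-12
        assert stats.spearmanr(out, x).statistic == pytest.approx(1.0)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_invariant_to_monotone_transforms(self, seed):
        x = np.random.default_rng(seed).normal(size=37)
        out = pica.force_normal(x)
        np.testing.assert_array_equal(out, pica.force_normal(np.exp(x)))
        np.testing.assert_array_equal(out, pica.force_normal(x ** 3))

    def test_applied_per_dataset(self):
        x = np.array([1.0, 2.0, 3.0, 10.0, 20.0, 30.0])
        ds = pd.Series(["a"] * 3 + ["b"] * 3, index=[f"s{i}" for i in range(6)])
        out = pica.force_normal(x, ds)
        np.testing.assert_allclose(out[:3], out[3:], atol=1e-12)

    def test_missing_values_stay_missing(self):
        x = np.array([1.0, np.nan, 2.0, 3.0])
        out = pica.force_normal(x)
        assert np.isnan(out[1]) and np.isfinite(out[[0, 2, 3]]).all()

    def test_too_few_values_per_dataset_raises(self):
        with pytest.raises(ValueError, match="2 non-missing"):
            pica.force_normal([1.0, np.nan])
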