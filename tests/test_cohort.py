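"""Inverse normal transform, covariate adjustment, cohort correlations."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from revtwmr import (
    CohortData,
    CollinearCovariatesError,
    DegenerateInputError,
    SimConfig,
    adjust_covariates,
    inverse_normal_transform,
    meta_correlations,
    pheno_expr_corr,
    simulate_cohort,
)
from revtwmr.cohort import ObsCorrelation


class TestInverseNormalTransform:
    def test_blom_quantiles_n3(self):
        out = inverse_normal_transform([10.0, 30.0, 20.0])
        expected = stats.norm.ppf((np.array([1, 3, 2]) - 0.375) / 3.25)
        assert out == pytest.approx(expected)
        # the Blom probability points themselves
        assert (np.array([1, 3, 2]) - 0.375) / 3.25 == pytest.approx(
            [0.1923, 0.8077, 0.5], abs=1e-4
        )

    def test_invariant_to_monotone_transform(self, rng):
        x = rng.uniform(1, 10, 100)
        assert inverse_normal_transform(np.exp(x)) == pytest.approx(
            inverse_normal_transform(x)
        )

    def test_ties_get_average_ranks(self):
        out = inverse_normal_transform([1.0, 1.0, 5.0])
        assert out[0] == out[1]
        assert out[2] > 0

    def test_large_sample_is_standard_normal(self, rng):
        x = rng.exponential(2.0, 20000)
        out = inverse_normal_transform(x)
        assert stats.kstest(out, "norm").statistic < 0.01

    def test_constant_input_rejected(self):
        with pytest.raises(DegenerateInputError):
            inverse_normal_transform([2.0, 2.0, 2.0])


class TestAdjustCovariates:
    def test_orthogonal_outcome_only_demeaned(self, rng):
        n = 200
        X = pd.DataFrame({"c": rng.standard_normal(n)})
        y = rng.standard_normal(n)
        y -= X["c"].to_numpy() * (y @ X["c"]) / (X["c"] @ X["c"])  # orthogonalize
        resid = adjust_covariates(y, X)
        # residuals orthogonal to every covariate column and the intercept
        assert abs(resid @ X["c"].to_numpy()) < 1e-8 * n
        assert abs(resid.sum()) < 1e-8 * n

    def test_exact_linear_combination_vanishes(self, rng):
        X = pd.DataFrame(rng.standard_normal((100, 3)), columns=list("abc"))
        y = 2 * X["a"] - X["b"] + 0.5 * X["c"] + 3.0
        resid = adjust_covariates(y.to_numpy(), X)
        assert np.max(np.abs(resid)) < 1e-10

    def test_matches_normal_equations_oracle(self, rng):
        X = pd.DataFrame(rng.standard_normal((80, 4)))
        y = rng.standard_normal(80)
        resid = adjust_covariates(y, X)
        X1 = np.column_stack([np.ones(80), X.to_numpy()])
        oracle = y - X1 @ np.linalg.solve(X1.T @ X1, X1.T @ y)
        assert resid == pytest.approx(oracle, abs=1e-10)

    def test_collinear_columns_named(self, rng):
        a = rng.standard_normal(50)
        X = pd.DataFrame({"a": a, "b": 2 * a})
        with pytest.raises(CollinearCovariatesError):
            adjust_covariates(rng.standard_normal(50), X)


class TestPhenoExprCorr:
    def _cohort(self, rng, expr, pheno=None, n=None):
        n = n or expr.shape[0]
        return CohortData(
            phenotype=pheno if pheno is not None else rng.standard_normal(n),
            covariates=pd.DataFrame({
                "sex": rng.integers(0, 2, n).astype(float),
                "age": rng.normal(50, 10, n),
            }),
            expression=expr,
            gene_ids=[f"g{i}" for i in range(expr.shape[1])],
            cohort_id="c1",
        )

    def test_identical_signal_gives_unit_correlation(self, rng):
        pheno = rng.standard_normal(300)
        cors, _ = pheno_expr_corr(self._cohort(rng, pheno[:, None], pheno=pheno))
        assert cors[0].r == pytest.approx(1.0, abs=1e-6)

    def test_independent_gene_in_null_band(self, rng):
        n = 500
        expr = rng.standard_normal((n, 20))
        cors, _ = pheno_expr_corr(self._cohort(rng, expr))
        rs = np.array([c.r for c in cors])
        assert np.all(np.abs(rs) < 4 / math.sqrt(n))
        assert np.all([c.se_r > 0 for c in cors])

    def test_confounder_driven_correlation_matches_model(self):
        """q_T = q_E = 0.3 with no causal effects: E[r] = 0.09."""
        cfg = SimConfig(seed=5, n_genes=60, n_individuals=4000, q_t=0.3, q_e=0.3)
        cohort, truth = simulate_cohort(cfg)
        cors, _ = pheno_expr_corr(cohort)
        rs = np.array([c.r for c in cors])
        se_mean = rs.std(ddof=1) / math.sqrt(rs.size)
        assert rs.mean() == pytest.approx(0.09, abs=3 * se_mean + 0.005)

    def test_zero_variance_gene_skipped(self, rng):
        expr = rng.standard_normal((100, 3))
        expr[:, 1] = 7.0
        cors, skipped = pheno_expr_corr(self._cohort(rng, expr))
        assert [c.gene_id for c in cors] == ["g0", "g2"]
        assert skipped == [("g1", "zero expression variance")]


class TestMetaCorrelations:
    def _oc(self, gene, r, n, cohort):
        se = math.sqrt((1 - r**2) / (n - 2))
        return ObsCorrelation(gene_id=gene, r=r, se_r=se, n=n, cohort_id=cohort)

    def test_identical_estimates_pass_through(self):
        per = [[self._oc("g1", 0.3, 500, "a")], [self._oc("g1", 0.3, 700, "b")]]
        (meta,) = meta_correlations(per)
        assert meta.r == pytest.approx(0.3)
        assert meta.cohort_id == "meta"

    def test_hand_checked_fisher_weights(self):
        r1, r2 = math.tanh(0.1), math.tanh(0.2)
        per = [[self._oc("g1", r1, 100, "a")], [self._oc("g1", r2, 400, "b")]]
        (meta,) = meta_correlations(per)
        expected_z = (97 * 0.1 + 397 * 0.2) / 494
        assert math.atanh(meta.r) == pytest.approx(expected_z)
        assert meta.n == 500

    def test_single_cohort_is_identity(self):
        per = [[self._oc("g1", -0.12, 300, "a")]]
        (meta,) = meta_correlations(per)
        assert meta.r == pytest.approx(-0.12)

    def test_meta_se_shrinks_with_total_sample(self, rng):
        """Three cohorts sized like the replication panel: SE ~ 1/sqrt(sum(n-3))."""
        sizes = (488, 609, 991)
        per = [[self._oc("g1", 0.1, n, f"c{i}")] for i, n in enumerate(sizes)]
        (meta,) = meta_correlations(per)
        expected_se = (1 - meta.r**2) / math.sqrt(sum(n - 3 for n in sizes))
        assert meta.se_r == pytest.approx(expected_se)

    def test_full_pipeline_recovers_generating_correlation(self):
        """Simulated three-cohort panel: meta r near structural truth."""
        sizes = (488, 609, 991)
        per_cohort = []
        for i, n in enumerate(sizes):
            cfg = SimConfig(seed=100 + i, n_genes=30, n_individuals=n,
                            alpha_rev=0.1, q_t=0.4, q_e=0.4)
            cohort, truth = simulate_cohort(cfg, cohort_id=f"c{i}")
            cors, _ = pheno_expr_corr(cohort)
            per_cohort.append(cors)
        meta = meta_correlations(per_cohort)
        rs = np.array([m.r for m in meta])
        target = truth.corr_true[0]  # 0.1 + 0.16 = 0.26
        assert rs.mean() == pytest.approx(target, abs=3 * rs.std(ddof=1) / math.sqrt(rs.size) + 0.01)

    def test_observational_tracks_reverse_effects_qualitatively(self):
        """Across genes, observational r correlates with alpha_rev when it
        varies and not when it is zero — the structure behind the trait table."""
        rng = np.random.default_rng(2024)
        n_genes = 80
        a_rev = rng.uniform(0.0, 0.3, n_genes)
        cfg = SimConfig(seed=55, n_genes=n_genes, n_individuals=3000,
                        alpha_rev=a_rev, q_t=0.0, q_e=0.0)
        cohort, _ = simulate_cohort(cfg)
        cors, _ = pheno_expr_corr(cohort)
        rs = np.array([c.r for c in cors])
        assert np.corrcoef(rs, a_rev)[0, 1] > 0.8

        cfg0 = SimConfig(seed=56, n_genes=n_genes, n_individuals=3000,
                         alpha_rev=0.0, q_t=0.0, q_e=0.0)
        cohort0, _ = simulate_cohort(cfg0)
        cors0, _ = pheno_expr_corr(cohort0)
        rs0 = np.array([c.r for c in cors0])
        assert abs(np.corrcoef(rs0, rng.permutation(a_rev))[0, 1]) < 0.3
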