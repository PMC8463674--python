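"""IVW estimator, delta-method variance, robust estimators, thresholds."""

import numpy as np
import pytest
from scipy import stats

from revtwmr import (
    DegenerateInstrumentsError,
    EXPRESSION_TO_TRAIT,
    TRAIT_TO_EXPRESSION,
    InstrumentSet,
    bonferroni_threshold,
    delta_variance,
    ivw_estimate,
    run_direction,
    simulate_summary_stats,
    weighted_median,
    weighted_mode,
    z_and_p,
    SimConfig,
)

from conftest import random_iset


def make_iset(beta, gamma, se_beta=0.01, se_gamma=0.01, ld=None):
    n = len(beta)
    se_b = np.full(n, se_beta) if np.isscalar(se_beta) else np.asarray(se_beta)
    se_g = np.full(n, se_gamma) if np.isscalar(se_gamma) else np.asarray(se_gamma)
    return InstrumentSet(
        gene_id="g", trait_id="t",
        snp_ids=tuple(f"rs{i}" for i in range(n)),
        beta=np.asarray(beta, float), se_beta=se_b,
        gamma=np.asarray(gamma, float), se_gamma=se_g,
        ld=ld,
    )


class TestIvw:
    def test_single_snp_is_ratio(self):
        est = ivw_estimate(make_iset([0.5], [0.25]))
        assert est.alpha == pytest.approx(0.5)

    def test_zero_outcome_effects_give_zero(self):
        est = ivw_estimate(make_iset([0.1, 0.2], [0.0, 0.0]))
        assert est.alpha == 0.0

    def test_matches_no_intercept_least_squares(self):
        est = ivw_estimate(make_iset([0.1, 0.2, 0.3], [0.05, 0.08, 0.12]))
        # oracle: no-intercept least-squares slope of gamma on beta
        beta = np.array([0.1, 0.2, 0.3])
        gamma = np.array([0.05, 0.08, 0.12])
        slope = float(np.linalg.lstsq(beta[:, None], gamma, rcond=None)[0][0])
        assert est.alpha == pytest.approx(slope)
        assert est.alpha == pytest.approx(0.4071428571, rel=1e-9)

    def test_all_zero_beta_degenerate(self):
        with pytest.raises(DegenerateInstrumentsError):
            ivw_estimate(make_iset([0.0, 0.0], [0.1, 0.2]))

    def test_identity_ld_reproduces_plain_form(self, rng):
        for _ in range(50):
            iset = random_iset(rng)
            with_ld = make_iset(iset.beta, iset.gamma, iset.se_beta, iset.se_gamma,
                                ld=np.eye(iset.n_snps))
            a = ivw_estimate(iset)
            b = ivw_estimate(with_ld)
            assert abs(a.alpha - b.alpha) < 1e-12
            assert abs(a.se_alpha - b.se_alpha) < 1e-12

    def test_correlated_instruments_change_estimate(self, rng):
        iset = random_iset(rng, n_snps=4)
        C = np.full((4, 4), 0.3) + 0.7 * np.eye(4)
        with_ld = make_iset(iset.beta, iset.gamma, iset.se_beta, iset.se_gamma, ld=C)
        # oracle: generalized least squares slope
        ci = np.linalg.inv(C)
        expected = (iset.beta @ ci @ iset.gamma) / (iset.beta @ ci @ iset.beta)
        assert ivw_estimate(with_ld).alpha == pytest.approx(expected, rel=1e-10)

    def test_singular_ld_raises_with_condition_number(self):
        C = np.ones((3, 3))  # perfectly correlated: singular
        np.fill_diagonal(C, 1.0)
        iset = make_iset([0.1, 0.2, 0.3], [0.05, 0.1, 0.15], ld=C)
        with pytest.raises(np.linalg.LinAlgError, match="condition number"):
            ivw_estimate(iset)

    def test_scale_equivariance(self, rng):
        iset = random_iset(rng)
        base = ivw_estimate(iset).alpha
        double_gamma = make_iset(iset.beta, 2 * iset.gamma, iset.se_beta, iset.se_gamma)
        assert ivw_estimate(double_gamma).alpha == pytest.approx(2 * base)
        double_beta = make_iset(2 * iset.beta, iset.gamma, iset.se_beta, iset.se_gamma)
        assert ivw_estimate(double_beta).alpha == pytest.approx(base / 2)

    def test_permutation_invariance(self, rng):
        iset = random_iset(rng, n_snps=12)
        perm = rng.permutation(12)
        shuffled = make_iset(iset.beta[perm], iset.gamma[perm],
                             iset.se_beta[perm], iset.se_gamma[perm])
        assert ivw_estimate(shuffled).alpha == pytest.approx(ivw_estimate(iset).alpha)


class TestDeltaVariance:
    def test_zero_ses_give_zero_variance(self):
        iset = make_iset([0.1, 0.2], [0.03, 0.06], se_beta=0.0, se_gamma=0.0)
        assert delta_variance(iset, 0.3) == 0.0

    def test_single_exact_snp_variance_is_outcome_variance(self):
        # beta known exactly: alpha_hat = gamma_hat so var(alpha) = var(gamma)
        iset = make_iset([1.0], [0.4], se_beta=0.0, se_gamma=0.1)
        assert delta_variance(iset, 0.4) == pytest.approx(0.01)

    def test_matches_monte_carlo(self, rng):
        """First-order variance within 5% of resampling variance."""
        beta_true = np.array([0.12, -0.2, 0.15, 0.09, -0.11])
        alpha = 0.3
        se_b, se_g = 0.004, 0.01
        gamma_true = alpha * beta_true
        iset = make_iset(beta_true, gamma_true, se_b, se_g)
        analytic = delta_variance(iset, alpha)
        B = 40000
        bb = beta_true + se_b * rng.standard_normal((B, 5))
        gg = gamma_true + se_g * rng.standard_normal((B, 5))
        alphas = np.sum(bb * gg, axis=1) / np.sum(bb * bb, axis=1)
        assert analytic == pytest.approx(np.var(alphas), rel=0.05)


class TestZandP:
    def test_null_point(self):
        assert z_and_p(0.0, 1.0) == (0.0, pytest.approx(1.0))

    def test_normal_quantile(self):
        z, p = z_and_p(1.959964, 1.0)
        assert p == pytest.approx(0.05, rel=1e-5)

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            z_and_p(1.0, 0.0)

    def test_pvalues_uniform_under_null(self, rng):
        zs = rng.standard_normal(20000)
        ps = np.array([z_and_p(z, 1.0)[1] for z in zs])
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestWeightedMedian:
    def test_constant_ratios_recovered_regardless_of_weights(self, rng):
        beta = rng.uniform(0.05, 0.3, 7)
        est = weighted_median(make_iset(beta, 0.4 * beta, se_gamma=rng.uniform(0.005, 0.02, 7)))
        assert est.alpha == pytest.approx(0.4)

    def test_robust_to_single_outlier(self):
        beta = np.array([0.1, 0.1, 0.1, 0.1, 0.1])
        gamma = np.array([0.030, 0.031, 0.029, 0.030, 0.30])  # one gross outlier
        est = weighted_median(make_iset(beta, gamma))
        assert 0.28 <= est.alpha <= 0.32  # within the concordant ratios' range

    def test_matches_brute_force_percentile_scan(self, rng):
        beta = rng.uniform(0.05, 0.3, 7)
        gamma = rng.normal(0.3 * beta, 0.01)
        se_g = rng.uniform(0.005, 0.02, 7)
        iset = make_iset(beta, gamma, se_gamma=se_g)
        est = weighted_median(iset, n_boot=10)
        # oracle: dense scan of the interpolated cumulative-weight function
        ratios = gamma / beta
        w = beta**2 / se_g**2
        order = np.argsort(ratios)
        r_sorted, w_sorted = ratios[order], w[order]
        p = (np.cumsum(w_sorted) - 0.5 * w_sorted) / w_sorted.sum()
        grid = np.linspace(r_sorted[0], r_sorted[-1], 200001)
        cdf_on_grid = np.interp(grid, r_sorted, p)
        expected = grid[np.argmin(np.abs(cdf_on_grid - 0.5))]
        assert est.alpha == pytest.approx(expected, abs=1e-4)

    def test_zero_beta_snp_excluded(self, caplog):
        beta = np.array([0.0, 0.1, 0.1, 0.1])
        gamma = np.array([0.5, 0.03, 0.03, 0.03])
        with caplog.at_level("WARNING", logger="revtwmr"):
            est = weighted_median(make_iset(beta, gamma), n_boot=10)
        assert est.alpha == pytest.approx(0.3)
        assert est.n_snps_used == 3


class TestWeightedMode:
    def test_constant_ratios_point_mass(self):
        beta = np.array([0.1, 0.2, 0.3])
        est = weighted_mode(make_iset(beta, 0.25 * beta), n_boot=10)
        assert est.alpha == pytest.approx(0.25)

    def test_plurality_cluster_recovered(self, rng):
        beta = np.full(10, 0.2)
        ratios = np.array([0.3] * 6 + [0.9] * 4) + rng.normal(0, 0.005, 10)
        est = weighted_mode(make_iset(beta, ratios * beta), n_boot=10)
        assert est.alpha == pytest.approx(0.3, abs=0.05)

    def test_permutation_invariance(self, rng):
        iset = random_iset(rng, n_snps=9)
        perm = rng.permutation(9)
        shuffled = make_iset(iset.beta[perm], iset.gamma[perm],
                             iset.se_beta[perm], iset.se_gamma[perm])
        a = weighted_mode(iset, n_boot=10, seed=7)
        b = weighted_mode(shuffled, n_boot=10, seed=7)
        assert a.alpha == pytest.approx(b.alpha, abs=1e-12)


class TestBonferroni:
    def test_transcriptome_wide_threshold(self):
        assert bonferroni_threshold(0.05, 19942) == pytest.approx(2.5e-6, rel=0.01)

    def test_single_test_passthrough(self):
        assert bonferroni_threshold(0.05, 1) == 0.05

    def test_robust_associations_threshold(self):
        assert bonferroni_threshold(0.05, 51) == pytest.approx(0.05 / 51)

    def test_invalid_count_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)


class TestRunDirection:
    def test_truth_recovery_over_causal_panel(self):
        """Mean reverse estimate over causal genes near the generating effect."""
        from revtwmr import eqtl_records_from_frame, gwas_records_from_frame

        alpha = np.array([0.2] * 10 + [0.0] * 40)
        cfg = SimConfig(seed=11, n_genes=50, alpha_rev=alpha)
        out = simulate_summary_stats(cfg, include_forward=False)
        gwas = gwas_records_from_frame(out.gwas_table)
        eqtl = eqtl_records_from_frame(out.eqtl_table)
        res = run_direction(gwas, eqtl, cfg.gene_ids, TRAIT_TO_EXPRESSION)
        by_gene = {e.gene_id: e for e in res.estimates}
        causal = [by_gene[g].alpha for g in cfg.gene_ids[:10]]
        null = [by_gene[g].alpha for g in cfg.gene_ids[10:]]
        se_mean = np.std(causal, ddof=1) / np.sqrt(len(causal))
        assert abs(np.mean(causal) - 0.2) < 3 * se_mean + 1e-9
        assert abs(np.mean(null)) < 0.02

    def test_direction_swap_recovers_each_truth(self):
        from revtwmr import eqtl_records_from_frame, gwas_records_from_frame

        cfg = SimConfig(seed=13, n_genes=20, alpha_rev=0.15, alpha_fwd=0.05)
        out = simulate_summary_stats(cfg)
        rev = run_direction(
            gwas_records_from_frame(out.gwas_table),
            eqtl_records_from_frame(out.eqtl_table),
            cfg.gene_ids, TRAIT_TO_EXPRESSION,
        )
        fwd = run_direction(
            gwas_records_from_frame(out.fwd_gwas_table),
            eqtl_records_from_frame(out.fwd_eqtl_table),
            cfg.gene_ids, EXPRESSION_TO_TRAIT,
        )
        rev_alphas = [e.alpha for e in rev.estimates]
        fwd_alphas = [e.alpha for e in fwd.estimates]
        assert np.mean(rev_alphas) == pytest.approx(0.15, abs=0.03)
        assert np.mean(fwd_alphas) == pytest.approx(0.05, abs=0.01)

    def test_empty_gene_list_is_empty_success(self):
        from revtwmr import eqtl_records_from_frame, gwas_records_from_frame

        cfg = SimConfig(seed=17, n_genes=2)
        out = simulate_summary_stats(cfg, include_forward=False)
        res = run_direction(
            gwas_records_from_frame(out.gwas_table),
            eqtl_records_from_frame(out.eqtl_table),
            [], TRAIT_TO_EXPRESSION,
        )
        assert res.estimates == [] and res.failures == []

    def test_failed_gene_reported_with_reason(self):
        from revtwmr import eqtl_records_from_frame, gwas_records_from_frame

        cfg = SimConfig(seed=19, n_genes=2)
        out = simulate_summary_stats(cfg, include_forward=False)
        res = run_direction(
            gwas_records_from_frame(out.gwas_table),
            eqtl_records_from_frame(out.eqtl_table),
            ["NOT_A_GENE"], TRAIT_TO_EXPRESSION,
        )
        assert res.estimates == []
        assert res.failures[0].gene_id == "NOT_A_GENE"
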