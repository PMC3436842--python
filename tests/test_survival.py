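"""Cox machinery: baselines, residuals, log-rank, screen, FDR."""

import numpy as np
import pytest

from coxmdr.survival import (
    DegenerateDataError,
    MonotoneLikelihoodError,
    bh_fdr,
    cox_fit,
    fit_cox_null,
    fit_cox_single_snp,
    logrank,
)

from conftest import make_cohort, random_cohort


# ----------------------------------------------------------------------
# Brute-force oracle: Breslow log partial likelihood on a coefficient grid.


def breslow_loglik_grid(time, status, x, grid):
    """Literal Breslow log partial likelihood for a single predictor,
    evaluated on a grid of coefficients (loops over event times)."""
    time, status, x = map(np.asarray, (time, status, x))
    ll = np.zeros(len(grid))
    for i, b in enumerate(grid):
        eta = b * x
        total = 0.0
        for t in np.unique(time[status == 1]):
            events = (time == t) & (status == 1)
            at_risk = time >= t
            d = events.sum()
            total += eta[events].sum() - d * np.log(np.exp(eta[at_risk]).sum())
        ll[i] = total
    return ll


class TestCoxNull:
    def test_nelson_aalen_closed_form(self, toy3):
        nf = fit_cox_null(toy3)
        np.testing.assert_allclose(nf.cum_baseline.jumps, [1 / 3, 1 / 2, 1])
        np.testing.assert_allclose(nf.residuals, [2 / 3, 1 / 6, -5 / 6])
        assert abs(nf.residuals.sum()) < 1e-12

    def test_all_censored_zero_residuals(self):
        co = make_cohort([1.0, 2.0, 5.0], [0, 0, 0])
        nf = fit_cox_null(co)
        np.testing.assert_array_equal(nf.residuals, 0.0)
        assert nf.cum_baseline(10.0) == 0.0

    def test_gamma_matches_grid_search_oracle(self):
        time = [1.0, 2.0, 3.0, 4.0, 5.0]
        status = [1, 1, 1, 1, 1]
        z = np.array([1.0, 0.0, 1.0, 0.0, 0.0])
        co = make_cohort(time, status, covariates=z[:, None])
        nf = fit_cox_null(co, covariates="all")
        grid = np.arange(-5, 5, 1e-4)
        ll = breslow_loglik_grid(time, status, z, grid)
        assert abs(nf.gamma[0] - grid[np.argmax(ll)]) < 1e-3

    def test_no_events_with_covariate_fails(self):
        co = make_cohort([1.0, 2.0], [0, 0], covariates=np.ones((2, 1)))
        with pytest.raises(DegenerateDataError):
            fit_cox_null(co, covariates="all")

    def test_monotone_likelihood_detected(self):
        # predictor strictly decreasing in event order: likelihood is
        # monotone in the coefficient, no finite MLE
        time = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        z = np.array([6.0, 5.0, 4.0, 3.0, 2.0, 1.0])
        co = make_cohort(time, [1] * 6, covariates=z[:, None])
        with pytest.raises(MonotoneLikelihoodError):
            fit_cox_null(co, covariates="all")

    @pytest.mark.parametrize("q", [0, 1, 2])
    def test_residual_invariants_random_cohorts(self, rng, q):
        for _ in range(10):
            co = random_cohort(rng, n=40, q=q)
            nf = fit_cox_null(co, covariates="all" if q else None)
            assert abs(nf.residuals.sum()) < 1e-8
            assert (nf.residuals <= 1 + 1e-12).all()
            assert (nf.residuals[co.status == 0] <= 1e-12).all()
            jumps = nf.cum_baseline.jumps
            assert (jumps >= 0).all()  # non-decreasing step function

    def test_loglik_not_below_null(self, rng):
        for _ in range(5):
            co = random_cohort(rng, n=40, q=2)
            fit = cox_fit(co.time, co.status, co.covariates)
            assert fit.loglik >= fit.loglik_null - 1e-10

    def test_matches_lifelines(self, rng):
        import pandas as pd
        from lifelines import CoxPHFitter

        co = random_cohort(rng, n=60, q=2)
        co.time += rng.random(60) * 1e-6  # break ties: Breslow == Efron
        nf = fit_cox_null(co, covariates="all")
        df = pd.DataFrame({"T": co.time, "E": co.status,
                           "z0": co.covariates[:, 0], "z1": co.covariates[:, 1]})
        cph = CoxPHFitter().fit(df, "T", "E")
        np.testing.assert_allclose(nf.gamma, cph.params_.values, atol=1e-4)
        mart = cph.compute_residuals(df, "martingale")["martingale"]
        np.testing.assert_allclose(nf.residuals,
                                   mart.reindex(df.index).values, atol=1e-3)


class TestLogrank:
    def test_hand_computed_risk_table(self):
        # group1 {(1,event),(3,cens)}, group2 {(2,event),(4,event)}
        r = logrank([1, 3, 2, 4], [1, 0, 1, 1], [True, True, False, False])
        assert r.observed_minus_expected == pytest.approx(1 / 6)
        assert r.variance == pytest.approx(17 / 36)

    def test_label_swap_negates_o_minus_e(self, rng):
        time = rng.exponential(1, 20)
        status = (rng.random(20) < 0.8).astype(int)
        g = rng.random(20) < 0.5
        g[0], g[1] = True, False  # both groups non-empty
        a = logrank(time, status, g)
        b = logrank(time, status, ~g)
        assert b.observed_minus_expected == pytest.approx(-a.observed_minus_expected)
        assert b.chi_square == pytest.approx(a.chi_square)

    def test_identical_groups_give_zero(self):
        time = [1, 2, 3, 1, 2, 3]
        status = [1, 0, 1, 1, 0, 1]
        r = logrank(time, status, [True, True, True, False, False, False])
        assert r.observed_minus_expected == pytest.approx(0.0, abs=1e-12)

    def test_matches_lifelines(self, rng):
        from lifelines.statistics import logrank_test

        time = rng.exponential(1, 50) + rng.random(50) * 1e-9
        status = (rng.random(50) < 0.7).astype(int)
        g = rng.random(50) < 0.4
        r = logrank(time, status, g)
        ll = logrank_test(time[g], time[~g], status[g], status[~g])
        assert r.chi_square == pytest.approx(ll.test_statistic, rel=1e-8)
        assert r.p_value == pytest.approx(ll.p_value, rel=1e-8)

    def test_empty_group_rejected(self):
        with pytest.raises(DegenerateDataError):
            logrank([1, 2], [1, 1], [True, True])


class TestSingleSnp:
    def test_collinear_with_covariate_fails(self):
        g = np.array([0, 1, 2, 0, 1, 2])
        co = make_cohort([1, 2, 3, 4, 5, 6], [1] * 6,
                         covariates=g[:, None].astype(float),
                         genotypes=g[:, None])
        with pytest.raises(DegenerateDataError):
            fit_cox_single_snp(co, 0, covariates="all")

    def test_constant_snp_fails(self):
        co = make_cohort([1, 2, 3], [1, 1, 1],
                         genotypes=np.ones((3, 1), dtype=int))
        with pytest.raises(DegenerateDataError):
            fit_cox_single_snp(co, 0)

    def test_coefficient_matches_grid_oracle(self):
        time = [2.0, 5.0, 1.0, 4.0, 3.0, 6.0]
        status = [1, 1, 1, 0, 1, 1]
        g = np.array([2, 0, 1, 1, 0, 0])
        co = make_cohort(time, status, genotypes=g[:, None])
        r = fit_cox_single_snp(co, 0)
        grid = np.arange(-5, 5, 1e-4)
        ll = breslow_loglik_grid(time, status, g, grid)
        assert abs(r["coef"] - grid[np.argmax(ll)]) < 1e-3

    def test_recovers_unit_log_hazard_ratio(self, rng):
        n = 5000
        g = rng.choice(3, size=n, p=[0.64, 0.32, 0.04])
        time = rng.exponential(1.0, n) / np.exp(1.0 * g)
        co = make_cohort(time + 1e-9, np.ones(n, int), genotypes=g[:, None])
        r = fit_cox_single_snp(co, 0)
        assert abs(r["coef"] - 1.0) < 3 * r["se"]

    def test_missing_genotypes_excluded(self, rng):
        co = random_cohort(rng, n=40, M=1)
        co.genotypes[:5, 0] = -1
        r = fit_cox_single_snp(co, 0)
        assert r["n_used"] == 35


class TestBhFdr:
    # the 21 screen p-values of a 139-SNP univariate scan and the adjusted
    # values they should reproduce (m = 139)
    SCREEN_P = [0.0029, 0.0033, 0.0118, 0.0118, 0.0118, 0.0118, 0.0118,
                0.0118, 0.0128, 0.0128, 0.0128, 0.0133, 0.0134, 0.0138,
                0.0146, 0.0151, 0.0228, 0.0264, 0.0380, 0.0447, 0.0467]
    SCREEN_FDR = [0.1313] * 16 + [0.1866, 0.2038, 0.2780, 0.3093, 0.3093]

    def test_single_p_is_identity(self):
        assert bh_fdr([0.03], 1)[0] == pytest.approx(0.03)

    def test_reproduces_139_snp_screen(self):
        adj = bh_fdr(self.SCREEN_P, m_total=139)
        np.testing.assert_allclose(adj, self.SCREEN_FDR, atol=5e-4)

    def test_step_up_monotone_and_above_raw(self, rng):
        p = rng.random(25)
        adj = bh_fdr(p)
        assert (adj >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()

    def test_permutation_invariance(self, rng):
        p = rng.random(15)
        perm = rng.permutation(15)
        np.testing.assert_allclose(bh_fdr(p, 40)[perm], bh_fdr(p[perm], 40))

    def test_invalid_p_rejected(self):
        with pytest.raises(DegenerateDataError):
            bh_fdr([0.5, 1.2])
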