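"""Additive SNP-MMR regression, Cook's diagnostics, BH FDR, QQ envelope."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mmrkit.association import (bh_fdr, compare_covariate_adjustment,
                                cooks_sensitivity, fit_additive_model,
                                qq_envelope)


def series(vals, name="x"):
    return pd.Series(np.asarray(vals, dtype=float),
                     index=[f"s{i}" for i in range(len(vals))], name=name)


class TestFitAdditiveModel:
    def test_exact_line_through_three_points(self):
        fit = fit_additive_model(series([0.0, 1.5, 3.0]), series([0, 1, 2]))
        assert fit.beta == pytest.approx(1.5, abs=1e-12)
        assert abs(fit.model.resid).max() < 1e-12

    def test_orthogonal_outcome_gives_zero_beta(self):
        # y = (1, -2, 1) is orthogonal to both the constant and x = (0, 1, 2)
        fit = fit_additive_model(series([1.0, -2.0, 1.0]), series([0, 1, 2]))
        assert fit.beta == pytest.approx(0.0, abs=1e-12)

    def test_constant_dosage_flagged_untestable(self):
        fit = fit_additive_model(series([1, 2, 3, 4, 5]), series([1, 1, 1, 1, 1]))
        assert not fit.testable
        assert np.isnan(fit.beta)

    def test_missing_dosage_rows_dropped_and_counted(self):
        y = series([0.0, 1.5, 3.0, 9.9, 4.5])
        x = series([0, 1, 2, np.nan, 3])
        fit = fit_additive_model(y, x)
        assert fit.n_used == 4
        assert fit.beta == pytest.approx(1.5, abs=1e-12)

    def test_singular_design_names_collinear_columns(self):
        y = series(np.arange(8.0))
        x = series([0, 1, 2, 0, 1, 2, 0, 1])
        cov = pd.DataFrame({"c1": x.to_numpy() * 2.0, "c2": np.arange(8.0)},
                           index=x.index)
        with pytest.raises(ValueError, match="collinear"):
            fit_additive_model(y, x, cov)

    def test_recovers_simulated_per_allele_effect(self, rng):
        n, beta_true = 2000, 3.0
        dosage = rng.binomial(2, 0.3, n).astype(float)
        poor = (rng.random(n) < 0.1).astype(float)
        y = 1.0 + beta_true * dosage + 2.0 * poor + rng.normal(0, 5.0, n)
        fit = fit_additive_model(series(y), series(dosage),
                                 pd.DataFrame({"poor_speller": poor},
                                              index=[f"s{i}" for i in range(n)]))
        assert abs(fit.beta - beta_true) < 3 * fit.se


class TestCooks:
    def test_perfect_line_all_distances_zero(self):
        y = series(np.arange(10) * 2.0 + 1.0)
        x = series(np.arange(10) % 3)
        y = series((x.to_numpy() * 2.0) + 1.0)
        fit = fit_additive_model(y, x)
        d, refit, shift = cooks_sensitivity(fit)
        assert np.allclose(d, 0.0, atol=1e-20)
        assert refit is None and shift == 0.0

    def test_gross_outlier_has_max_distance_above_threshold(self, rng):
        n = 30
        x = series(np.tile([0, 1, 2], 10))
        y_vals = 1.5 * x.to_numpy() + rng.normal(0, 0.1, n)
        y_vals[-1] += 25.0
        fit = fit_additive_model(series(y_vals), x)
        d, refit, shift = cooks_sensitivity(fit)
        assert np.argmax(d) == n - 1
        assert d[-1] > 4.0 / n
        assert refit is not None
        assert abs(refit.beta - 1.5) < abs(fit.beta - 1.5)  # refit is cleaner

    def test_distance_matches_leave_one_out_refit_oracle(self, rng):
        n = 12
        x = series(rng.integers(0, 3, n).astype(float))
        y = series(1.0 + 2.0 * x.to_numpy() + rng.normal(0, 1.0, n))
        fit = fit_additive_model(y, x)
        d, _, _ = cooks_sensitivity(fit)
        import statsmodels.api as sm
        X = fit.model.model.exog
        yv = fit.model.model.endog
        p = X.shape[1]
        s2 = fit.model.mse_resid
        yhat = fit.model.fittedvalues
        for i in range(n):
            keep = np.arange(n) != i
            loo = sm.OLS(yv[keep], X[keep]).fit()
            yhat_loo = X @ loo.params
            d_oracle = ((yhat - yhat_loo) ** 2).sum() / (p * s2)
            assert d[i] == pytest.approx(d_oracle, rel=1e-8)


class TestBHFDR:
    def test_published_top_ranks_reach_five_percent(self):
        p = np.array([0.0037, 0.0039, 0.0146, 0.0157, 0.0199])
        q = bh_fdr(p, m=25)
        assert q[0] == pytest.approx(0.04875)
        assert q[1] == pytest.approx(0.04875)

    def test_single_p_value_scales_by_m(self):
        assert bh_fdr(np.array([0.5]), m=1)[0] == pytest.approx(0.5)
        assert bh_fdr(np.array([0.02]), m=10)[0] == pytest.approx(0.2)

    def test_all_equal_collapse_verified_by_formula(self):
        p = np.full(4, 0.01)
        q = bh_fdr(p, m=8)
        assert np.allclose(q, 8 * 0.01 / 4)

    def test_equals_bruteforce_stepup_on_random_vectors(self, rng):
        def brute(p, m):
            n = len(p)
            order = np.argsort(p)
            q = np.empty(n)
            for rank_pos, idx in enumerate(order):
                q[idx] = min(min(m * p[order[j]] / (j + 1), 1.0)
                             for j in range(rank_pos, n))
            return q

        for _ in range(1000):
            n = rng.integers(1, 15)
            p = rng.uniform(1e-6, 1.0, n)
            m = int(n + rng.integers(0, 10))
            assert np.allclose(bh_fdr(p, m=m), brute(p, m))

    def test_matches_statsmodels_when_m_equals_n(self, rng):
        from statsmodels.stats.multitest import multipletests
        p = rng.uniform(1e-6, 1, 40)
        assert np.allclose(bh_fdr(p), multipletests(p, method="fdr_bh")[1])

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr(np.array([0.0, 0.5]))
        with pytest.raises(ValueError):
            bh_fdr(np.array([1.2]))
        with pytest.raises(ValueError, match="smaller"):
            bh_fdr(np.array([0.1, 0.2]), m=1)


class TestQQEnvelope:
    def test_single_test_is_uniform(self):
        env = qq_envelope(1)
        assert env.loc[1, "expected"] == pytest.approx(0.5)
        assert env.loc[1, "lower"] == pytest.approx(0.025)
        assert env.loc[1, "upper"] == pytest.approx(0.975)

    def test_rank_one_lower_bound_closed_form(self):
        # Beta(1, 25) quantile: F(x) = 1-(1-x)^25 -> x = 1 - 0.975^(1/25)
        env = qq_envelope(25)
        assert env.loc[1, "lower"] == pytest.approx(1 - 0.975 ** (1 / 25), rel=1e-9)
        assert env.loc[1, "lower"] == pytest.approx(0.001012, abs=5e-6)

    def test_bounds_bracket_expectation_and_increase_with_rank(self):
        env = qq_envelope(25)
        assert (env["lower"] < env["expected"]).all()
        assert (env["expected"] < env["upper"]).all()
        for col in ("expected", "lower", "upper"):
            assert env[col].is_monotonic_increasing

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            qq_envelope(0)
        with pytest.raises(ValueError):
            qq_envelope(10, level=1.0)


class TestCovariateComparison:
    def make_results(self, rng, with_signal_cov=False):
        n = 300
        idx = [f"s{i}" for i in range(n)]
        dosage = pd.Series(rng.binomial(2, 0.3, n).astype(float), index=idx)
        poor = pd.Series((rng.random(n) < 0.2).astype(float), index=idx)
        add = pd.Series((rng.random(n) < 0.2).astype(float), index=idx)
        y = pd.Series(2.0 * dosage.to_numpy() + rng.normal(0, 1, n), index=idx)
        if with_signal_cov:
            y = y + 3.0 * add
        base = fit_additive_model(y, dosage, pd.DataFrame({"poor_speller": poor}))
        withc = fit_additive_model(y, dosage, pd.DataFrame({"poor_speller": poor,
                                                            "add_status": add}))
        def frame(fit):
            return pd.DataFrame({"beta": [fit.beta], "p": [fit.p]}, index=["snp1"])
        return frame(base), frame(withc)

    def test_orthogonal_covariate_leaves_estimates_stable(self, rng):
        base, withc = self.make_results(rng, with_signal_cov=False)
        deltas = compare_covariate_adjustment(base, withc)
        assert abs(deltas["beta_delta"].iloc[0]) < 0.15

    def test_outcome_only_covariate_moves_p_not_beta(self, rng):
        base, withc = self.make_results(rng, with_signal_cov=True)
        deltas = compare_covariate_adjustment(base, withc)
        assert abs(deltas["beta_delta"].iloc[0]) < 0.25
        assert deltas["p_with_add"].iloc[0] < deltas["p_base"].iloc[0]

    def test_mismatched_snp_sets_rejected(self):
        a = pd.DataFrame({"beta": [1.0], "p": [0.1]}, index=["snp1"])
        b = pd.DataFrame({"beta": [1.0], "p": [0.1]}, index=["snp2"])
        with pytest.raises(ValueError, match="SNP sets"):
            compare_covariate_adjustment(a, b)
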