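"""PRS scoring, logistic combiner, AUC with DeLong CI, NRI and IDI."""

import numpy as np
import pandas as pd
import pytest

from mmrkit.panel import load_panel, scored_snps
from mmrkit.prediction import (compare_models, compute_prs, fit_logistic, idi,
                               nri_continuous, roc_auc)


class TestPRS:
    def test_homozygous_risk_everywhere_scores_forty(self, panel):
        snps = scored_snps(panel)
        assert len(snps) == 20
        g = pd.DataFrame(2.0, index=["a", "b"], columns=list(panel.index))
        score = compute_prs(g, panel)
        assert (score.prs == 40.0).all()
        assert score.n_snps_scored == 20

    def test_heterozygous_everywhere_scores_twenty(self, panel):
        g = pd.DataFrame(1.0, index=["a"], columns=list(panel.index))
        assert compute_prs(g, panel).prs.iloc[0] == 20.0

    def test_missing_dosage_imputed_with_snp_mean(self, panel):
        snps = scored_snps(panel)
        n = 10
        g = pd.DataFrame(0.0, index=[f"i{k}" for k in range(n)],
                         columns=list(panel.index))
        # SNP mean dosage among the others = 0.6 (maf 0.3 under HWE)
        g.loc[:, snps[0]] = [np.nan] + [2.0] * 3 + [0.0] * 6
        g.iloc[1:, 0] = g.iloc[1:, 0]
        score = compute_prs(g, panel)
        others_mean = g[snps[0]].iloc[1:].mean()
        assert others_mean == pytest.approx(2.0 / 3)
        assert score.prs.iloc[0] == pytest.approx(others_mean)
        assert ("i0", snps[0]) in score.imputed

    def test_unscorable_panel_rejected(self, panel):
        g = pd.DataFrame(1.0, index=["a"], columns=["rs000000"])
        with pytest.raises(ValueError, match="scorable"):
            compute_prs(g, panel)


class TestLogistic:
    def test_binary_predictor_slope_equals_log_odds_ratio(self):
        # exposed: 40 events / 10 non-events; unexposed: 10 / 40 -> OR = 16
        y = np.array([1] * 40 + [0] * 10 + [1] * 10 + [0] * 40)
        x = np.array([1.0] * 50 + [0.0] * 50)
        probs = fit_logistic(y, x)
        p1, p0 = probs[0], probs[-1]
        slope = np.log(p1 / (1 - p1)) - np.log(p0 / (1 - p0))
        assert slope == pytest.approx(np.log(16.0), rel=1e-6)

    def test_uninformative_predictor_gives_prevalence(self, rng):
        y = np.array([1] * 30 + [0] * 70)
        x = rng.standard_normal(100)
        probs = fit_logistic(y, x)
        assert probs.mean() == pytest.approx(0.3, abs=1e-6)  # MLE calibration
        assert probs.std() < 0.15

    def test_single_class_outcome_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            fit_logistic(np.ones(10), np.arange(10.0))

    def test_perfect_separation_warns_but_returns_probabilities(self):
        y = np.array([0, 0, 0, 1, 1, 1])
        x = np.arange(6.0)
        with pytest.warns(UserWarning, match="separation"):
            probs = fit_logistic(y, x)
        assert probs.shape == (6,)
        assert probs[:3].max() < 0.5 < probs[3:].min()


class TestAUC:
    def test_perfectly_separated_scores(self):
        auc, _ = roc_auc(np.array([1, 2, 3, 11, 12, 13]),
                         np.array([0, 0, 0, 1, 1, 1]))
        assert auc == 1.0

    def test_pure_ties_give_half(self):
        auc, _ = roc_auc(np.ones(10), np.array([0, 1] * 5))
        assert auc == pytest.approx(0.5)

    def test_enumerated_pairs_example(self):
        # cases {3, 2}, controls {1, 2.5}: 3 of 4 pairs concordant
        auc, _ = roc_auc(np.array([3.0, 2.0, 1.0, 2.5]), np.array([1, 1, 0, 0]))
        assert auc == pytest.approx(0.75)

    def test_delong_ci_matches_pROC_oracle(self):
        # frozen reference from R pROC ci.auc(..., method="delong")
        scores = np.array([0.1, 0.4, 0.35, 0.8, 0.7, 0.2,
                           0.55, 0.9, 0.65, 0.3, 0.45, 0.75])
        labels = np.array([0, 0, 1, 1, 1, 0, 0, 1, 1, 0, 0, 1])
        auc, (lo, hi) = roc_auc(scores, labels)
        assert auc == pytest.approx(0.9166666667, abs=1e-9)
        assert lo == pytest.approx(0.7377472523, abs=1e-9)
        assert hi == pytest.approx(1.0, abs=1e-9)

    def test_bootstrap_ci_brackets_point_estimate(self, rng):
        scores = rng.standard_normal(60) + np.repeat([0.0, 1.0], 30)
        labels = np.repeat([0, 1], 30)
        auc, (lo, hi) = roc_auc(scores, labels, ci_method="bootstrap")
        assert lo <= auc <= hi

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc(np.arange(5.0), np.zeros(5))


class TestNRI:
    def test_identical_models_zero(self):
        p = np.linspace(0.1, 0.9, 6)
        y = np.array([0, 1, 0, 1, 0, 1])
        with pytest.warns(UserWarning, match="degenerate"):
            nri, z, pval = nri_continuous(p, p.copy(), y)
        assert nri == 0.0 and pval == 1.0

    def test_direct_enumeration_example(self):
        # events move (+, +, -), nonevents move (-, -):
        # NRI = (2/3 - 1/3) + (1 - 0) = 4/3
        p_old = np.array([0.5, 0.5, 0.5, 0.5, 0.5])
        p_new = np.array([0.6, 0.7, 0.4, 0.3, 0.2])
        y = np.array([1, 1, 1, 0, 0])
        nri, z, pval = nri_continuous(p_old, p_new, y)
        assert nri == pytest.approx(4.0 / 3.0)
        assert z > 0 and 0 < pval < 1

    def test_all_events_rejected(self):
        with pytest.raises(ValueError, match="nonevents"):
            nri_continuous(np.array([0.3, 0.4]), np.array([0.5, 0.6]),
                           np.array([1, 1]))


class TestIDI:
    def test_identical_models_zero(self):
        p = np.linspace(0.1, 0.9, 6)
        y = np.array([0, 1, 0, 1, 0, 1])
        with pytest.warns(UserWarning, match="degenerate"):
            value, z, pval = idi(p, p.copy(), y)
        assert value == 0.0

    def test_constructed_slope_change_equals_point_one(self, rng):
        # old slope 0.2, new slope 0.3 by construction (with within-class
        # jitter so the variance is defined)
        n = 40
        y = np.repeat([1, 0], n // 2)
        jit = rng.uniform(-0.01, 0.01, n)
        p_old = np.where(y == 1, 0.5, 0.3) + jit
        p_new = np.where(y == 1, 0.6, 0.3) + jit
        value, z, pval = idi(p_old, p_new, y)
        assert value == pytest.approx(0.1, abs=1e-12)
        assert z > 0

    def test_anti_informative_model_negative(self):
        y = np.array([1, 1, 0, 0])
        p_old = np.array([0.8, 0.7, 0.2, 0.3])
        p_new = np.array([0.55, 0.45, 0.5, 0.5])
        value, _, _ = idi(p_old, p_new, y)
        assert value < 0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="events"):
            idi(np.array([0.3, 0.4]), np.array([0.5, 0.6]), np.array([0, 0]))


class TestCompareModels:
    def test_study_sized_dataset_emits_all_fields(self, rng):
        n, events = 67, 14
        y = pd.Series(np.r_[np.ones(events), np.zeros(n - events)],
                      index=[f"s{i}" for i in range(n)])
        mmr = pd.Series(rng.normal(0, 2, n) + 3.0 * y.to_numpy(), index=y.index)
        prs = pd.Series(rng.binomial(40, 0.4, n).astype(float), index=y.index)
        cmp = compare_models(mmr, prs, y)
        assert 0.5 < cmp.auc_mmr <= 1.0
        assert cmp.ci_mmr[0] <= cmp.auc_mmr <= cmp.ci_mmr[1]
        assert cmp.n == 67 and cmp.n_events == 14
        d = cmp.to_dict()
        for key in ("auc_mmr", "auc_prs", "auc_combined", "nri_cont", "idi",
                    "nri_p", "idi_p"):
            assert key in d

    def test_informative_prs_raises_combined_auc(self, rng):
        n = 400
        y = pd.Series((rng.random(n) < 0.3).astype(int),
                      index=[f"s{i}" for i in range(n)])
        mmr = pd.Series(rng.normal(0, 1, n) + 1.0 * y, index=y.index)
        prs = pd.Series(rng.normal(0, 1, n) + 1.0 * y, index=y.index)
        cmp = compare_models(mmr, prs, y)
        assert cmp.auc_combined > cmp.auc_mmr
        assert cmp.nri_cont > 0 and cmp.idi > 0
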