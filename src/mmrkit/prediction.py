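"""Polygenic risk score and classifier comparison (AUC, continuous NRI, IDI).

The unweighted PRS is the per-individual sum of risk-allele dosages over the
panel SNPs that carry a literature risk allele (20 of the 25 candidates in
the packaged panel); missing dosages are imputed with the per-SNP mean.
Poor-spelling status is then predicted by logistic models on the late MMR
alone, the PRS alone, and both together.  Discrimination is summarised by
the ROC AUC (Mann-Whitney statistic, ties at one half) with a DeLong
confidence interval; the added value of the PRS over the MMR-only model by
the continuous net reclassification improvement (any directional change in
predicted risk) and the integrated discrimination improvement (difference
in discrimination slopes), each with its asymptotic z-test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .panel import scored_snps


@dataclass
class RiskScore:
    """Per-individual unweighted risk-allele count."""

    prs: pd.Series
    n_snps_scored: int
    imputed: dict = field(default_factory=dict)  # (individual, rsid) -> imputed dosage


def compute_prs(genotypes: pd.DataFrame, panel: pd.DataFrame) -> RiskScore:
    """Sum risk-allele dosages over the scorable panel SNPs.

    Only SNPs with a literature risk allele contribute; missing dosages are
    replaced by the SNP's mean dosage (2 x allele frequency) and recorded.
    """
    snps = [s for s in scored_snps(panel) if s in genotypes.columns]
    if not snps:
        raise ValueError("no scorable SNPs: panel risk alleles missing or "
                         "no overlap with the genotype matrix")
    sub = genotypes[snps]
    imputed = {}
    means = sub.mean(axis=0)
    filled = sub.copy()
    for snp in snps:
        missing = sub[snp].isna()
        if missing.any():
            filled.loc[missing, snp] = means[snp]
            imputed.update({(str(i), snp): float(means[snp])
                            for i in sub.index[missing]})
    return RiskScore(prs=filled.sum(axis=1), n_snps_scored=len(snps), imputed=imputed)


def fit_logistic(outcome: pd.Series | np.ndarray, predictors: pd.DataFrame | np.ndarray,
                 tol: float = 1e-8, maxiter: int = 100) -> np.ndarray:
    """Maximum-likelihood logistic fit; returns fitted probabilities.

    Newton/IRLS with tolerance 1e-8.  Perfect separation is flagged with a
    warning and probabilities are still returned from an L-BFGS fit.
    """
    y = np.asarray(outcome, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("outcome must contain both classes")
    X = np.asarray(predictors, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    X = sm.add_constant(X)
    from statsmodels.tools.sm_exceptions import (ConvergenceWarning,
                                                 PerfectSeparationWarning)

    model = sm.Logit(y, X)
    separated = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            res = model.fit(method="newton", tol=tol, maxiter=maxiter, disp=False)
        except np.linalg.LinAlgError:
            separated = True
            res = model.fit(method="lbfgs", maxiter=500, disp=False)
    separated = separated or any(issubclass(w.category, PerfectSeparationWarning)
                                 for w in caught)
    for w in caught:  # keep non-separation diagnostics visible
        if not issubclass(w.category, (PerfectSeparationWarning, ConvergenceWarning)):
            warnings.warn_explicit(w.message, w.category, w.filename, w.lineno)
    if separated:
        warnings.warn("perfect separation detected; fitted probabilities are degenerate")
    return np.asarray(res.predict(X))


def roc_auc(scores: np.ndarray, labels: np.ndarray, ci_method: str = "delong",
            level: float = 0.95) -> tuple[float, tuple[float, float]]:
    """ROC AUC as the Mann-Whitney concordance probability, with CI.

    Ties count one half.  The default CI is DeLong's asymptotic interval
    (clipped to [0, 1]); ``ci_method='bootstrap'`` draws 2000 stratified
    resamples instead.
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("need both classes for an AUC")
    auc, var = _delong_auc_variance(s, y)
    z = stats.norm.ppf(0.5 + level / 2.0)
    if ci_method == "delong":
        half = z * np.sqrt(var)
        ci = (max(0.0, auc - half), min(1.0, auc + half))
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(0)
        cases, controls = s[y == 1], s[y == 0]
        boots = np.empty(2000)
        for b in range(2000):
            cb = rng.choice(cases, len(cases))
            nb = rng.choice(controls, len(controls))
            boots[b] = _auc_mann_whitney(cb, nb)
        tail = (1.0 - level) / 2.0
        ci = tuple(np.quantile(boots, [tail, 1.0 - tail]))
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    return float(auc), (float(ci[0]), float(ci[1]))


def _auc_mann_whitney(cases: np.ndarray, controls: np.ndarray) -> float:
    """Pairwise concordance with ties at 1/2 via the rank-sum statistic."""
    all_scores = np.concatenate([cases, controls])
    ranks = stats.rankdata(all_scores)
    n1, n0 = len(cases), len(controls)
    return float((ranks[:n1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def _delong_auc_variance(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """DeLong (1988) AUC and asymptotic variance via midrank placements."""
    cases = scores[labels == 1]
    controls = scores[labels == 0]
    m, n = len(cases), len(controls)
    # placement of each case among controls and vice versa
    v10 = np.array([(np.sum(c > controls) + 0.5 * np.sum(c == controls)) / n
                    for c in cases])
    v01 = np.array([(np.sum(cases > c0) + 0.5 * np.sum(cases == c0)) / m
                    for c0 in controls])
    auc = v10.mean()
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return float(auc), float(s10 / m + s01 / n)


def nri_continuous(p_old: np.ndarray, p_new: np.ndarray, labels: np.ndarray
                   ) -> tuple[float, float, float]:
    """Continuous (category-free) net reclassification improvement.

    NRI = [P(up|event) - P(down|event)] + [P(down|nonevent) - P(up|nonevent)]
    with up/down any nonzero change of predicted risk; z by the standard
    asymptotic variance.  Returns (nri, z, p).
    """
    p_old, p_new, y = (np.asarray(a, dtype=float) for a in (p_old, p_new, labels))
    _check_probs(p_old, p_new, y)
    dif = p_new - p_old
    ev, ne = dif[y == 1], dif[y == 0]
    if len(ev) == 0 or len(ne) == 0:
        raise ValueError("need both events and nonevents")
    up_ev, down_ev = np.mean(ev > 0), np.mean(ev < 0)
    up_ne, down_ne = np.mean(ne > 0), np.mean(ne < 0)
    nri = (up_ev - down_ev) + (down_ne - up_ne)
    var = (up_ev + down_ev - (up_ev - down_ev) ** 2) / len(ev) \
        + (up_ne + down_ne - (down_ne - up_ne) ** 2) / len(ne)
    if var <= 0:
        if nri == 0:
            warnings.warn("no reclassification in either direction; NRI degenerate")
            return 0.0, 0.0, 1.0
        return float(nri), float("inf"), 0.0
    z = nri / np.sqrt(var)
    return float(nri), float(z), float(2 * stats.norm.sf(abs(z)))


def idi(p_old: np.ndarray, p_new: np.ndarray, labels: np.ndarray
        ) -> tuple[float, float, float]:
    """Integrated discrimination improvement.

    IDI = discrimination slope(new) - discrimination slope(old), where the
    slope is mean(p|event) - mean(p|nonevent); z from the paired-difference
    standard errors within events and nonevents.  Returns (idi, z, p).
    """
    p_old, p_new, y = (np.asarray(a, dtype=float) for a in (p_old, p_new, labels))
    _check_probs(p_old, p_new, y)
    ev, ne = y == 1, y == 0
    if not ev.any() or not ne.any():
        raise ValueError("need both events and nonevents")
    d_ev = p_new[ev] - p_old[ev]
    d_ne = p_new[ne] - p_old[ne]
    value = d_ev.mean() - d_ne.mean()
    se = np.sqrt((d_ev.var(ddof=1) / len(d_ev) if len(d_ev) > 1 else 0.0)
                 + (d_ne.var(ddof=1) / len(d_ne) if len(d_ne) > 1 else 0.0))
    if se == 0:
        if value == 0:
            warnings.warn("identical models; IDI degenerate")
            return 0.0, 0.0, 1.0
        return float(value), float("inf"), 0.0
    z = value / se
    return float(value), float(z), float(2 * stats.norm.sf(abs(z)))


def _check_probs(p_old, p_new, y):
    if p_old.shape != p_new.shape or p_old.shape != y.shape:
        raise ValueError("p_old, p_new and labels must have equal length")
    for name, p in (("p_old", p_old), ("p_new", p_new)):
        if np.any((p < 0) | (p > 1)):
            raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class ModelComparison:
    """AUCs (with CIs) of the three risk models and PRS-added reclassification."""

    auc_mmr: float
    ci_mmr: tuple[float, float]
    auc_prs: float
    ci_prs: tuple[float, float]
    auc_combined: float
    ci_combined: tuple[float, float]
    nri_cont: float
    nri_z: float
    nri_p: float
    idi: float
    idi_z: float
    idi_p: float
    n: int
    n_events: int

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in
             ("auc_mmr", "auc_prs", "auc_combined", "nri_cont", "nri_z",
              "nri_p", "idi", "idi_z", "idi_p", "n", "n_events")}
        d["ci_mmr"], d["ci_prs"], d["ci_combined"] = self.ci_mmr, self.ci_prs, self.ci_combined
        return d


def compare_models(mmr: pd.Series, prs: pd.Series, labels: pd.Series,
                   ci_method: str = "delong") -> ModelComparison:
    """Compare MMR-alone, PRS-alone and combined logistic risk models.

    Inputs are aligned on their index (complete cases).  NRI and IDI compare
    the MMR-alone model (old) with the combined model (new).
    """
    df = pd.DataFrame({"mmr": mmr, "prs": prs, "y": labels}).dropna()
    y = df["y"].astype(int).to_numpy()
    p_mmr = fit_logistic(y, df[["mmr"]])
    p_prs = fit_logistic(y, df[["prs"]])
    p_both = fit_logistic(y, df[["mmr", "prs"]])
    auc_m, ci_m = roc_auc(p_mmr, y, ci_method)
    auc_p, ci_p = roc_auc(p_prs, y, ci_method)
    auc_b, ci_b = roc_auc(p_both, y, ci_method)
    nri, nri_z, nri_p = nri_continuous(p_mmr, p_both, y)
    idi_v, idi_z, idi_p = idi(p_mmr, p_both, y)
    return ModelComparison(
        auc_mmr=auc_m, ci_mmr=ci_m, auc_prs=auc_p, ci_prs=ci_p,
        auc_combined=auc_b, ci_combined=ci_b,
        nri_cont=nri, nri_z=nri_z, nri_p=nri_p,
        idi=idi_v, idi_z=idi_z, idi_p=idi_p,
        n=len(df), n_events=int(y.sum()))
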