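"""Per-SNP additive association of the late MMR, FDR control and QQ envelope.

Each SNP is tested in an ordinary least-squares model

    MMR_i = beta0 + beta * dosage_i + gamma * poor_speller_i (+ delta * ADD_i) + e_i

with dosage in copies of the panel risk allele (additive coding), so ``beta``
is the change of the late-MMR window mean (uV) per risk allele.  P-values
are two-sided; multiplicity is controlled by Benjamini-Hochberg step-up FDR
over the candidate panel.  Influence diagnostics use Cook's distance with a
conventional 4/n flag; calibration of the p-value distribution is assessed
with a QQ plot whose 95% envelope comes from the Beta order statistics of
uniform p-values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


@dataclass
class SnpFit:
    """One SNP's additive-model fit."""

    rsid: str
    beta: float
    se: float
    t: float
    p: float
    n_used: int
    testable: bool = True
    note: str = ""
    model: object | None = None  # statsmodels results, for diagnostics


def fit_additive_model(mmr: pd.Series, dosage: pd.Series,
                       covariates: pd.DataFrame | None = None,
                       rsid: str = "") -> SnpFit:
    """OLS fit of MMR on risk-allele dosage plus covariates.

    Rows with missing dosage (or any missing input) are dropped per SNP and
    ``n_used`` records the complete-case count.  A constant dosage is flagged
    untestable (NaN estimates) rather than raising; a singular covariate
    design raises with the offending columns named.
    """
    df = pd.DataFrame({"mmr": mmr, "dosage": dosage})
    if covariates is not None:
        for col in covariates.columns:
            df[col] = covariates[col].astype(float)
    df = df.dropna()
    n = len(df)
    n_params = df.shape[1]  # intercept + predictors (response column stands in for the constant)
    if n <= n_params:
        raise ValueError(f"too few complete cases (n={n}) for {n_params} parameters")
    if df["dosage"].nunique() <= 1:
        return SnpFit(rsid=rsid, beta=np.nan, se=np.nan, t=np.nan, p=np.nan,
                      n_used=n, testable=False, note="constant dosage")
    X = sm.add_constant(df.drop(columns="mmr"))
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        corr = X.drop(columns="const").corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        pair = np.unravel_index(np.argmax(corr.to_numpy()), corr.shape)
        raise ValueError("singular design matrix; collinear columns: "
                         f"{corr.index[pair[0]]}, {corr.columns[pair[1]]}")
    res = sm.OLS(df["mmr"], X).fit()
    return SnpFit(rsid=rsid, beta=float(res.params["dosage"]),
                  se=float(res.bse["dosage"]), t=float(res.tvalues["dosage"]),
                  p=float(res.pvalues["dosage"]), n_used=n, model=res)


def association_scan(mmr: pd.Series, genotypes: pd.DataFrame,
                     phenotypes: pd.DataFrame, adjust_add: bool = False,
                     fdr_m: int | None = None) -> pd.DataFrame:
    """Per-SNP additive fits adjusted for poor spelling (optionally ADD).

    Returns a DataFrame indexed by rsid with beta, se, t, p, fdr_q, n_used,
    testable; FDR is computed over the testable SNPs with ``m`` defaulting
    to their count.
    """
    cov_cols = ["poor_speller", "add_status"] if adjust_add else ["poor_speller"]
    covariates = phenotypes[cov_cols].astype(float)
    rows = []
    for snp in genotypes.columns:
        fit = fit_additive_model(mmr, genotypes[snp], covariates, rsid=str(snp))
        rows.append({"rsid": fit.rsid, "beta": fit.beta, "se": fit.se,
                     "t": fit.t, "p": fit.p, "n_used": fit.n_used,
                     "testable": fit.testable})
    out = pd.DataFrame(rows).set_index("rsid")
    mask = out["testable"] & out["p"].notna()
    out["fdr_q"] = np.nan
    if mask.any():
        out.loc[mask, "fdr_q"] = bh_fdr(out.loc[mask, "p"].to_numpy(), m=fdr_m)
    return out


def cooks_sensitivity(fit: SnpFit, threshold_rule: str = "4/n"
                      ) -> tuple[np.ndarray, SnpFit | None, float]:
    """Cook's distance screen and refit without influential observations.

    Observations with D > 4/n are flagged; the model is refit without them
    and the resulting change of the dosage coefficient returned.  If too few
    points remain for a refit, only the distances are reported.
    """
    if fit.model is None:
        raise ValueError("fit carries no model (untestable SNP?)")
    res = fit.model
    n = int(res.nobs)
    # an (all but) exact fit has no influential points; the raw formula would
    # divide ~0 residuals by a ~0 residual variance
    scale = float(np.var(res.model.endog)) or 1.0
    if res.mse_resid < 1e-24 * scale:
        cooks_d = np.zeros(n)
    else:
        cooks_d = res.get_influence().cooks_distance[0]
    if threshold_rule != "4/n":
        raise ValueError(f"unknown threshold rule {threshold_rule!r}")
    flagged = cooks_d > 4.0 / n
    if not flagged.any():
        return cooks_d, None, 0.0
    keep = ~flagged
    X, y = res.model.exog[keep], res.model.endog[keep]
    if keep.sum() <= X.shape[1] + 1:
        return cooks_d, None, float("nan")
    refit = sm.OLS(y, X).fit()
    names = res.model.exog_names
    beta_new = float(refit.params[names.index("dosage")])
    shift = beta_new - fit.beta
    new_fit = SnpFit(rsid=fit.rsid, beta=beta_new,
                     se=float(refit.bse[names.index("dosage")]),
                     t=float(refit.tvalues[names.index("dosage")]),
                     p=float(refit.pvalues[names.index("dosage")]),
                     n_used=int(refit.nobs), model=refit)
    return cooks_d, new_fit, shift


def bh_fdr(pvals: np.ndarray, m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values.

    ``m`` is the size of the test universe and may exceed ``len(pvals)``
    (partial p-value lists): q(i) = min_{k >= i} m * p(k) / k, capped at 1.
    Returned in the input order.
    """
    p = np.asarray(pvals, dtype=float)
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    n = len(p)
    if m is None:
        m = n
    if m < n:
        raise ValueError(f"m={m} smaller than number of p-values ({n})")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def qq_envelope(m: int, level: float = 0.95) -> pd.DataFrame:
    """Expected order statistics of m uniform p-values with a confidence band.

    Rank i of m has expectation i/(m+1) and distribution Beta(i, m-i+1);
    the band holds the (1-level)/2 and 1-(1-level)/2 Beta quantiles.  The
    report layer plots everything on the -log10 scale.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0, 1), got {level}")
    ranks = np.arange(1, m + 1)
    a, b = ranks, m - ranks + 1
    tail = (1.0 - level) / 2.0
    return pd.DataFrame({
        "rank": ranks,
        "expected": ranks / (m + 1.0),
        "lower": stats.beta.ppf(tail, a, b),
        "upper": stats.beta.ppf(1.0 - tail, a, b),
    }).set_index("rank")


def compare_covariate_adjustment(results_base: pd.DataFrame,
                                 results_with_add: pd.DataFrame) -> pd.DataFrame:
    """Per-SNP effect/p-value deltas between ADD-unadjusted and -adjusted fits."""
    if set(results_base.index) != set(results_with_add.index):
        raise ValueError("SNP sets differ between the two result tables")
    add = results_with_add.loc[results_base.index]
    return pd.DataFrame({
        "beta_base": results_base["beta"], "beta_with_add": add["beta"],
        "beta_delta": add["beta"] - results_base["beta"],
        "p_base": results_base["p"], "p_with_add": add["p"],
        "p_delta": add["p"] - results_base["p"],
    })
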