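"""Genotype quality control and LD-based clumping.

QC applies, in a fixed order, individual call rate, SNP call rate, minor
allele frequency and Hardy-Weinberg equilibrium filters; the HWE alpha is
Bonferroni-corrected by the number of SNPs entering the test.  Clumping
greedily picks the most strongly associated unassigned SNP as a clump index
and absorbs all SNPs correlated with it at r^2 >= threshold (optionally
within a physical window), keeping only index SNPs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln


@dataclass(frozen=True)
class QCThresholds:
    """Inclusion thresholds: HWE p > alpha/m, call rates and MAF strict."""

    hwe_alpha: float = 0.05
    snp_call_rate_min: float = 0.97
    ind_call_rate_min: float = 0.90
    maf_min: float = 0.05

    def __post_init__(self):
        for name in ("hwe_alpha", "snp_call_rate_min", "ind_call_rate_min", "maf_min"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")


@dataclass
class QCReport:
    """Per-SNP and per-individual diagnostics plus removal bookkeeping."""

    snp_stats: pd.DataFrame
    individual_stats: pd.DataFrame
    removed_snps: dict = field(default_factory=dict)  # rsid -> reason
    removed_individuals: dict = field(default_factory=dict)
    hwe_bonferroni_m: int = 0
    n_individuals_kept: int = 0
    n_snps_kept: int = 0


def hwe_test(n_hom_risk: int, n_het: int, n_hom_other: int,
             method: str = "chisq") -> float:
    """Hardy-Weinberg goodness-of-fit p-value from genotype counts.

    ``chisq``: 1-df chi-square against expectations at the sample allele
    frequency, no continuity correction.  ``exact``: conditional exact test
    summing the probabilities of all heterozygote counts no more probable
    than the observed one.  Monomorphic SNPs return p = 1.
    """
    counts = np.array([n_hom_risk, n_het, n_hom_other], dtype=float)
    if np.any(counts < 0):
        raise ValueError("genotype counts must be non-negative")
    n = counts.sum()
    if n <= 0:
        raise ValueError("total genotype count must be positive")
    p_allele = (2 * counts[0] + counts[1]) / (2 * n)
    if p_allele in (0.0, 1.0):
        return 1.0  # monomorphic
    if method == "chisq":
        q = 1 - p_allele
        expected = n * np.array([p_allele ** 2, 2 * p_allele * q, q ** 2])
        chi2 = float(((counts - expected) ** 2 / expected).sum())
        return float(stats.chi2.sf(chi2, df=1))
    if method == "exact":
        return _hwe_exact(int(n_hom_risk), int(n_het), int(n_hom_other))
    raise ValueError(f"unknown HWE method {method!r}")


def _hwe_exact(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Conditional exact HWE test (sum of het-count probabilities <= observed)."""
    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab
    n_rare = min(n_a, 2 * n - n_a)
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    # unnormalized log-probabilities of each possible heterozygote count
    n_aa_all = (n_rare - hets) // 2
    n_bb_all = n - n_aa_all - hets
    logp = (hets * np.log(2) - gammaln(n_aa_all + 1) - gammaln(hets + 1)
            - gammaln(n_bb_all + 1))
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    observed = probs[np.searchsorted(hets, n_ab)]  # parity of n_ab matches n_rare
    return float(min(1.0, probs[probs <= observed + 1e-12].sum()))


def genotype_counts(dosage: pd.Series) -> tuple[int, int, int]:
    """(hom risk, het, hom other) counts from a 0/1/2 dosage column."""
    d = dosage.dropna()
    return int((d == 2).sum()), int((d == 1).sum()), int((d == 0).sum())


def minor_allele_frequency(dosage: pd.Series) -> float:
    """MAF from dosages (folded risk-allele frequency)."""
    d = dosage.dropna()
    if len(d) == 0:
        return float("nan")
    p = d.mean() / 2.0
    return float(min(p, 1.0 - p))


def apply_qc(genotypes: pd.DataFrame, thresholds: QCThresholds = QCThresholds(),
             hwe_method: str = "chisq") -> tuple[pd.DataFrame, QCReport]:
    """Filter a dosage matrix (individuals x SNPs, NaN = missing call).

    Order of operations: individual call rate -> SNP call rate -> MAF ->
    HWE (Bonferroni m = SNPs entering the HWE stage).  Raises if nothing
    survives.
    """
    removed_ind: dict[str, str] = {}
    removed_snp: dict[str, str] = {}

    ind_cr = genotypes.notna().mean(axis=1)
    keep_ind = ind_cr > thresholds.ind_call_rate_min
    for ind in genotypes.index[~keep_ind]:
        removed_ind[str(ind)] = "ind_call_rate"
    g = genotypes.loc[keep_ind]
    if g.empty:
        raise ValueError("no individuals pass the call-rate filter")

    snp_cr = g.notna().mean(axis=0)
    for snp in g.columns[~(snp_cr > thresholds.snp_call_rate_min)]:
        removed_snp[str(snp)] = "snp_call_rate"
    g = g.loc[:, snp_cr > thresholds.snp_call_rate_min]

    maf = g.apply(minor_allele_frequency, axis=0)
    for snp in g.columns[~(maf > thresholds.maf_min)]:
        removed_snp[str(snp)] = "maf"
    g = g.loc[:, maf > thresholds.maf_min]

    m = g.shape[1]
    hwe_p = pd.Series({snp: hwe_test(*genotype_counts(g[snp]), method=hwe_method)
                       for snp in g.columns}, dtype=float)
    if m > 0:
        hwe_cut = thresholds.hwe_alpha / m
        for snp in g.columns[~(hwe_p > hwe_cut)]:
            removed_snp[str(snp)] = "hwe"
        g = g.loc[:, hwe_p > hwe_cut]
    if g.shape[1] == 0:
        raise ValueError("no SNPs pass QC")

    snp_stats = pd.DataFrame({
        "call_rate": genotypes.notna().mean(axis=0),
        "maf": genotypes.apply(minor_allele_frequency, axis=0),
    })
    snp_stats["hwe_p"] = hwe_p.reindex(snp_stats.index)
    snp_stats["pass"] = ~snp_stats.index.astype(str).isin(removed_snp)
    snp_stats["removal_reason"] = [removed_snp.get(str(s), "") for s in snp_stats.index]
    ind_stats = pd.DataFrame({"call_rate": ind_cr})
    ind_stats["pass"] = ~ind_stats.index.astype(str).isin(removed_ind)

    report = QCReport(snp_stats=snp_stats, individual_stats=ind_stats,
                      removed_snps=removed_snp, removed_individuals=removed_ind,
                      hwe_bonferroni_m=m, n_individuals_kept=g.shape[0],
                      n_snps_kept=g.shape[1])
    return g, report


def ld_clump(snp_stats: pd.DataFrame, r2_matrix: pd.DataFrame,
             r2_threshold: float = 0.5, window_kb: float | None = 250.0,
             positions: pd.Series | None = None,
             p_threshold_index: float = 1.0) -> list[str]:
    """Greedy LD clumping; returns the retained independent index SNPs.

    ``snp_stats`` needs a ``p`` column indexed by rsid; ``r2_matrix`` is the
    symmetric unit-diagonal pairwise r^2 table.  Repeatedly the unassigned
    SNP with the smallest p (<= ``p_threshold_index``) becomes an index and
    absorbs all unassigned SNPs with r^2 >= threshold (and, when positions
    are given, within ``window_kb``); absorbed SNPs are dropped, keeping the
    more strongly associated index of each clump.
    """
    snps = list(snp_stats.index)
    if list(r2_matrix.index) != snps or list(r2_matrix.columns) != snps:
        raise ValueError("r2_matrix must be indexed by the snp_stats rsIDs")
    r2 = r2_matrix.to_numpy()
    if not np.allclose(r2, r2.T) or not np.allclose(np.diag(r2), 1.0):
        raise ValueError("r2_matrix must be symmetric with unit diagonal")
    if window_kb is not None and positions is None:
        window_kb = None  # no positions -> window unenforceable

    pvals = snp_stats["p"].to_numpy(dtype=float)
    unassigned = set(range(len(snps)))
    index_snps: list[str] = []
    for i in np.argsort(pvals, kind="stable"):
        if i not in unassigned or pvals[i] > p_threshold_index:
            continue
        index_snps.append(snps[i])
        clumped = {i}
        for j in list(unassigned):
            if j == i or r2[i, j] < r2_threshold:
                continue
            if window_kb is not None:
                dist_kb = abs(positions[snps[i]] - positions[snps[j]]) / 1000.0
                if dist_kb > window_kb:
                    continue
            clumped.add(j)
        unassigned -= clumped
    return index_snps
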