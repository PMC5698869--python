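"""Report rendering: difference-wave figure, QQ plot, dosage boxplots, tables.

Every figure and table is regenerated purely from on-disk stage outputs.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .association import qq_envelope
from .erp.stats import group_average_with_ci

ASSOCIATION_COLUMNS = ["snp", "p", "fdr", "beta", "gene"]


def association_table(results: pd.DataFrame, panel: pd.DataFrame,
                      nominal_alpha: float = 0.05) -> pd.DataFrame:
    """Nominally associated SNPs, strongest first, with gene annotation."""
    sel = results[results["p"] < nominal_alpha].sort_values("p")
    return pd.DataFrame({
        "snp": sel.index,
        "p": sel["p"].round(4).to_numpy(),
        "fdr": sel["fdr_q"].round(2).to_numpy(),
        "beta": sel["beta"].round(1).to_numpy(),
        "gene": [panel.loc[s, "gene"] if s in panel.index else "" for s in sel.index],
    }).reset_index(drop=True)


def plot_difference_waves(waves_by_group: dict[str, np.ndarray], times_ms: np.ndarray,
                          path: str | Path, level: float = 0.95) -> None:
    """ROI-mean difference waves per group with t-based CI shading."""
    fig, ax = plt.subplots(figsize=(7, 4))
    for label, waves in waves_by_group.items():
        waves = np.atleast_2d(waves)
        if waves.shape[0] == 0:
            warnings.warn(f"group {label!r} empty; omitted from figure")
            continue
        if waves.shape[0] >= 2:
            mean, lo, hi = group_average_with_ci(waves, level)
            ax.fill_between(times_ms, lo, hi, alpha=0.25)
        else:
            mean = waves[0]
        ax.plot(times_ms, mean, label=f"{label} (n={waves.shape[0]})")
    ax.axhline(0.0, color="k", lw=0.5)
    ax.axvspan(300, 600, color="grey", alpha=0.12, label="late MMR window")
    ax.set_xlabel("time after stimulus onset (ms)")
    ax.set_ylabel("deviant - standard (uV)")
    ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_qq(pvals: np.ndarray, path: str | Path, level: float = 0.95) -> bool:
    """QQ plot of observed vs expected -log10 p with the order-statistic
    confidence envelope.  Returns False (and warns) when there is nothing
    to plot."""
    p = np.sort(np.asarray(pvals, dtype=float))
    p = p[np.isfinite(p)]
    if len(p) == 0:
        warnings.warn("no p-values; QQ plot skipped")
        return False
    env = qq_envelope(len(p), level)
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    x = -np.log10(env["expected"].to_numpy())
    ax.plot(x, -np.log10(p), "o", ms=4, label="observed")
    ax.plot(x, x, "k-", lw=0.8)
    ax.plot(x, -np.log10(env["lower"].to_numpy()), "k--", lw=0.8,
            label=f"{level:.0%} envelope")
    ax.plot(x, -np.log10(env["upper"].to_numpy()), "k--", lw=0.8)
    ax.set_xlabel("expected -log10 p")
    ax.set_ylabel("observed -log10 p")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return True


def plot_genotype_boxplots(mmr: pd.Series, genotypes: pd.DataFrame,
                           snps: list[str], path: str | Path) -> None:
    """Per-SNP boxplots of the late MMR by risk-allele count."""
    n = len(snps)
    fig, axes = plt.subplots(1, max(n, 1), figsize=(2.6 * max(n, 1), 3.2),
                             squeeze=False)
    for ax, snp in zip(axes[0], snps):
        groups = [mmr[genotypes[snp] == d].dropna() for d in (0, 1, 2)]
        ax.boxplot([g.to_numpy() for g in groups], tick_labels=["0", "1", "2"])
        ax.set_title(snp, fontsize=8)
        ax.set_xlabel("risk alleles", fontsize=8)
    axes[0][0].set_ylabel("late MMR (uV)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
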