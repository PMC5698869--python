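"""Group-level waveform statistics: sliding-window t-test and CI bands."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

#: sliding-test defaults: 375 windows of 3.2 ms tiling [0, 1200) ms
DEFAULT_WINDOW_MS = 3.2
DEFAULT_SPAN_MS = (0.0, 1200.0)


def _window_means(waves: np.ndarray, times_ms: np.ndarray,
                  edges: np.ndarray) -> np.ndarray:
    """Per-subject mean of each [edges[k], edges[k+1]) window.

    Windows shorter than the sampling step may contain no sample; those
    inherit the value of the sample nearest the window centre.
    """
    n_sub = waves.shape[0]
    out = np.empty((n_sub, len(edges) - 1))
    for k in range(len(edges) - 1):
        mask = (times_ms >= edges[k]) & (times_ms < edges[k + 1])
        if mask.any():
            out[:, k] = waves[:, mask].mean(axis=1)
        else:
            centre = 0.5 * (edges[k] + edges[k + 1])
            out[:, k] = waves[:, int(np.argmin(np.abs(times_ms - centre)))]
    return out


def sliding_ttest(waves_a: np.ndarray, waves_b: np.ndarray, times_ms: np.ndarray,
                  window_ms: float = DEFAULT_WINDOW_MS,
                  span_ms: tuple[float, float] = DEFAULT_SPAN_MS,
                  equal_var: bool = False) -> pd.DataFrame:
    """Welch (default) two-sample t-test in consecutive short time windows.

    ``waves_a`` / ``waves_b`` are (subjects x time) ROI-mean difference
    waves for the two groups.  The span is tiled into ``span/window``
    non-overlapping windows — 375 windows for [0, 1200) ms at 3.2 ms — and
    the test compares per-subject window means between groups.

    Returns a DataFrame with columns start_ms, end_ms, t, p.
    """
    if waves_a.shape[0] < 2 or waves_b.shape[0] < 2:
        raise ValueError("need >= 2 subjects per group")
    lo, hi = span_ms
    n_win = int(round((hi - lo) / window_ms))
    edges = lo + window_ms * np.arange(n_win + 1)
    ma = _window_means(np.atleast_2d(waves_a), times_ms, edges)
    mb = _window_means(np.atleast_2d(waves_b), times_ms, edges)
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(ma, mb, axis=0, equal_var=equal_var)
    # degenerate windows (zero variance in both groups): t undefined
    return pd.DataFrame({"start_ms": edges[:-1], "end_ms": edges[1:],
                         "t": t, "p": p})


def group_average_with_ci(waves: np.ndarray, level: float = 0.95
                          ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pointwise mean and t-based confidence band across subjects.

    Returns (mean, lower, upper); the band is mean +- t_{n-1} * SEM.
    """
    if not 0.0 < level < 1.0:
        raise ValueError(f"confidence level must be in (0, 1), got {level}")
    waves = np.atleast_2d(waves)
    n = waves.shape[0]
    if n < 2:
        raise ValueError("need >= 2 subjects for a confidence band")
    mean = waves.mean(axis=0)
    sem = waves.std(axis=0, ddof=1) / np.sqrt(n)
    q = stats.t.ppf(0.5 + level / 2.0, df=n - 1)
    return mean, mean - q * sem, mean + q * sem
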