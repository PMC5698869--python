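"""Epoching, artifact rejection and late-MMR quantification.

Epochs span [-200, 1250) ms around stimulus onset on the recording's
sampling grid (363 samples at 250 Hz), baseline-corrected by the mean of
[-200, 0) ms per channel.  Standards presented directly after a deviant are
excluded by design; trials exceeding +-80 uV (within any 200 ms window)
are invalid.  The scalar endophenotype is the mean of the deviant-minus-
standard difference wave over the anterior ROI (F3, Fz, F4) within
[300, 600) ms.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .containers import (REASON_ARTIFACT, REASON_EDGE, REASON_NONE,
                         REASON_STANDARD_AFTER_DEVIANT, ContinuousEEG,
                         DifferenceWave, EpochSet, MMRMeasure,
                         PreprocessConfig)

DEVIANT = "deviant"
STANDARD = "standard"


def epoch(eeg: ContinuousEEG, events: pd.DataFrame,
          config: PreprocessConfig = PreprocessConfig()) -> EpochSet:
    """Cut baseline-corrected epochs around the event onsets.

    Events whose epoch would run past either end of the recording are kept
    but flagged invalid (reason ``edge``); standards immediately following a
    deviant are flagged ``standard_after_deviant``.
    """
    dt_ms = 1000.0 / eeg.fs_hz
    e0, e1 = config.epoch_window_ms
    offsets = np.arange(int(np.floor(e0 / dt_ms + 1e-9)),
                        int(np.ceil(e1 / dt_ms - 1e-9)))
    times = offsets * dt_ms
    n_trials = len(events)
    n_ch = len(eeg.channel_labels)
    data = np.zeros((n_trials, n_ch, len(offsets)))
    valid = np.ones(n_trials, dtype=bool)
    reason = np.full(n_trials, REASON_NONE, dtype=object)

    condition = events["condition"].to_numpy()
    prev_deviant = np.concatenate(([False], condition[:-1] == DEVIANT))
    after_deviant = (condition == STANDARD) & prev_deviant

    onsets = events["onset_ms"].to_numpy()
    for i, onset in enumerate(onsets):
        base_idx = int(round(onset / dt_ms))
        lo, hi = base_idx + offsets[0], base_idx + offsets[-1]
        if lo < 0 or hi >= eeg.n_samples:
            valid[i] = False
            reason[i] = REASON_EDGE
            continue
        data[i] = eeg.samples[:, lo:hi + 1]
        if after_deviant[i]:
            valid[i] = False
            reason[i] = REASON_STANDARD_AFTER_DEVIANT

    b0, b1 = config.baseline_window_ms
    bmask = (times >= b0) & (times < b1)
    data -= data[:, :, bmask].mean(axis=2, keepdims=True)

    syllable = (events["syllable"].to_numpy() if "syllable" in events
                else np.full(n_trials, "", dtype=object))
    return EpochSet(data=data, times_ms=times, channel_labels=list(eeg.channel_labels),
                    condition=condition.astype(object), syllable=syllable,
                    valid=valid, excluded_reason=reason, fs_hz=eeg.fs_hz)


def reject_artifacts(epochs: EpochSet,
                     config: PreprocessConfig = PreprocessConfig()) -> EpochSet:
    """Flag trials exceeding the amplitude criterion.

    Default semantics: any sample with |x| > threshold within any 200 ms
    sliding window — for an absolute bound the window is immaterial, so this
    equals a global amplitude criterion.  ``reject_mode='peak_to_peak'``
    instead flags windows whose range exceeds 2x the threshold.
    """
    thr = config.reject_threshold_uv
    if config.reject_mode == "absolute":
        bad = np.abs(epochs.data).max(axis=(1, 2)) > thr
    else:
        w = max(1, int(round(config.reject_window_ms / 1000.0 * epochs.fs_hz)))
        sliding = np.lib.stride_tricks.sliding_window_view(epochs.data, w, axis=2)
        p2p = sliding.max(axis=3) - sliding.min(axis=3)
        bad = p2p.max(axis=(1, 2)) > 2 * thr
    valid = epochs.valid.copy()
    reason = epochs.excluded_reason.copy()
    fresh = bad & (reason == REASON_NONE)
    valid[fresh] = False
    reason[fresh] = REASON_ARTIFACT
    return EpochSet(data=epochs.data, times_ms=epochs.times_ms,
                    channel_labels=epochs.channel_labels, condition=epochs.condition,
                    syllable=epochs.syllable, valid=valid, excluded_reason=reason,
                    fs_hz=epochs.fs_hz)


def _condition_mean(epochs: EpochSet, condition: str,
                    syllable: str | None = None) -> tuple[np.ndarray, int]:
    mask = epochs.valid & (epochs.condition == condition)
    if syllable is not None:
        mask &= epochs.syllable == syllable
    n = int(mask.sum())
    if n == 0:
        raise ValueError(f"no valid {condition} trials"
                         + (f" for syllable {syllable!r}" if syllable else ""))
    return epochs.data[mask].mean(axis=0), n


def average_and_difference(epochs: EpochSet, contrast: str = "pooled",
                           subject_id: str = "") -> DifferenceWave:
    """Deviant-minus-standard average difference wave for one subject.

    ``pooled`` contrasts all valid deviants against all retained standards
    (both blocks together); ``matched`` computes the same-syllable contrast
    per syllable and averages the two syllable-specific differences.
    """
    if contrast == "pooled":
        dev, n_dev = _condition_mean(epochs, DEVIANT)
        std, n_std = _condition_mean(epochs, STANDARD)
        diff = dev - std
    elif contrast == "matched":
        syllables = sorted(set(epochs.syllable) - {""})
        parts, n_dev, n_std = [], 0, 0
        for syl in syllables:
            dev, nd = _condition_mean(epochs, DEVIANT, syl)
            std, ns = _condition_mean(epochs, STANDARD, syl)
            parts.append(dev - std)
            n_dev += nd
            n_std += ns
        diff = np.mean(parts, axis=0)
    else:
        raise ValueError(f"unknown contrast {contrast!r}")
    return DifferenceWave(
        data=diff, times_ms=epochs.times_ms, channel_labels=epochs.channel_labels,
        subject_id=subject_id, n_valid_deviant=n_dev, n_valid_standard=n_std,
        exclusion_fractions={DEVIANT: epochs.exclusion_fraction(DEVIANT),
                             STANDARD: epochs.exclusion_fraction(STANDARD)})


def mmr_amplitude(diff: DifferenceWave,
                  config: PreprocessConfig = PreprocessConfig()) -> MMRMeasure:
    """Scalar late MMR: ROI-mean of the window-mean of the difference wave."""
    try:
        roi_idx = [diff.channel_labels.index(ch) for ch in config.roi]
    except ValueError as err:
        raise KeyError(f"ROI channel missing from difference wave: {err}") from err
    w0, w1 = config.mmr_window_ms
    wmask = (diff.times_ms >= w0) & (diff.times_ms < w1)
    if not wmask.any():
        raise ValueError("MMR window contains no samples")
    value = float(diff.data[np.ix_(roi_idx, wmask)].mean())
    return MMRMeasure(
        subject_id=diff.subject_id, mmr_uv=value,
        n_valid_deviant=diff.n_valid_deviant, n_valid_standard=diff.n_valid_standard,
        exclusion_fraction_deviant=diff.exclusion_fractions.get(DEVIANT, float("nan")),
        exclusion_fraction_standard=diff.exclusion_fractions.get(STANDARD, float("nan")))


def compare_exclusion_rates(measures: list[MMRMeasure]) -> tuple[float, float]:
    """Paired two-sided t-test of artifact-exclusion fractions across subjects
    (standard vs deviant condition)."""
    if len(measures) < 2:
        raise ValueError("need >= 2 subjects for a paired test")
    std = np.array([m.exclusion_fraction_standard for m in measures])
    dev = np.array([m.exclusion_fraction_deviant for m in measures])
    diffs = std - dev
    if np.allclose(diffs, diffs[0]):
        if diffs[0] == 0:
            return 0.0, 1.0
        warnings.warn("zero variance of paired differences; p degenerate")
        return float("inf") * np.sign(diffs[0]), 0.0
    t, p = stats.ttest_rel(std, dev)
    return float(t), float(p)
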