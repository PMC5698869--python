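"""Per-subject processing chain: continuous EEG -> scalar late MMR.

Stage order follows the acquisition protocol: mastoid re-reference, 30 Hz
low-pass at the native rate, downsampling to 250 Hz, 0.5 Hz high-pass,
epoching with baseline correction and design exclusions, amplitude-based
artifact rejection, condition averaging, and ROI window-mean quantification.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import ContinuousEEG, DifferenceWave, EpochSet, MMRMeasure, PreprocessConfig
from .epochs import average_and_difference, epoch, mmr_amplitude, reject_artifacts
from .preprocess import FilterReport, filter_signal, rereference, resample


def preprocess_continuous(eeg: ContinuousEEG, config: PreprocessConfig
                          ) -> tuple[ContinuousEEG, list[FilterReport]]:
    """Re-reference, filter and resample one continuous recording."""
    reports: list[FilterReport] = []
    out = rereference(eeg, config.reference_labels)
    if config.lowpass_hz is not None:
        out, rep = filter_signal(out, "lowpass", config.lowpass_hz)
        reports.append(rep)
    if config.resample_hz is not None:
        out = resample(out, config.resample_hz)
    if config.highpass_hz is not None:
        out, rep = filter_signal(out, "highpass", config.highpass_hz)
        reports.append(rep)
    return out, reports


def epochs_from_recording(eeg: ContinuousEEG, events: pd.DataFrame,
                          config: PreprocessConfig) -> EpochSet:
    """Preprocess one recording and return rejected/flagged epochs."""
    clean, _ = preprocess_continuous(eeg, config)
    return reject_artifacts(epoch(clean, events, config), config)


def _concat_epochs(parts: list[EpochSet]) -> EpochSet:
    first = parts[0]
    for p in parts[1:]:
        if len(p.times_ms) != len(first.times_ms) or p.channel_labels != first.channel_labels:
            raise ValueError("epoch grids differ between blocks")
    return EpochSet(
        data=np.concatenate([p.data for p in parts]),
        times_ms=first.times_ms, channel_labels=first.channel_labels,
        condition=np.concatenate([p.condition for p in parts]),
        syllable=np.concatenate([p.syllable for p in parts]),
        valid=np.concatenate([p.valid for p in parts]),
        excluded_reason=np.concatenate([p.excluded_reason for p in parts]),
        fs_hz=first.fs_hz)


def process_subject(recordings: list[tuple[ContinuousEEG, pd.DataFrame]],
                    config: PreprocessConfig = PreprocessConfig(),
                    subject_id: str = "") -> tuple[MMRMeasure, DifferenceWave]:
    """Reduce a subject's block recordings to the late-MMR scalar.

    Blocks are preprocessed independently, epochs concatenated, and the
    deviant-minus-standard contrast computed per the configured mode.
    """
    parts = [epochs_from_recording(eeg, events, config) for eeg, events in recordings]
    epochs = _concat_epochs(parts)
    diff = average_and_difference(epochs, contrast=config.contrast, subject_id=subject_id)
    return mmr_amplitude(diff, config), diff


def roi_mean_wave(diff: DifferenceWave, roi: tuple[str, ...] = ("F3", "Fz", "F4")
                  ) -> np.ndarray:
    """Difference wave averaged over the anterior ROI channels."""
    idx = [diff.channel_labels.index(ch) for ch in roi]
    return diff.data[idx].mean(axis=0)


def measures_to_frame(measures: list[MMRMeasure]) -> pd.DataFrame:
    """Tabulate per-subject MMR measures (TSV-ready)."""
    rows = [{
        "subject_id": m.subject_id, "mmr_uv": m.mmr_uv,
        "n_valid_deviant": m.n_valid_deviant, "n_valid_standard": m.n_valid_standard,
        "exclusion_fraction_deviant": m.exclusion_fraction_deviant,
        "exclusion_fraction_standard": m.exclusion_fraction_standard,
    } for m in measures]
    return pd.DataFrame(rows).set_index("subject_id")
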