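"""In-memory containers for the ERP pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: exclusion reasons
REASON_NONE = "none"
REASON_ARTIFACT = "artifact"
REASON_STANDARD_AFTER_DEVIANT = "standard_after_deviant"
REASON_EDGE = "edge"


@dataclass
class ContinuousEEG:
    """Continuous multichannel recording in microvolts.

    ``samples`` is channels x time; channel labels are unique and case-
    sensitive as written (10-20 names, mastoids A1/A2).
    """

    samples: np.ndarray
    fs_hz: float
    channel_labels: list[str]
    reference_label: str = "Cz"

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[0] != len(self.channel_labels):
            raise ValueError("samples must be channels x time matching channel_labels")
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    def index_of(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError as err:
            raise KeyError(f"channel {label!r} not in recording "
                           f"({', '.join(self.channel_labels)})") from err

    def copy_with(self, **kw) -> "ContinuousEEG":
        return replace(self, **kw)


@dataclass(frozen=True)
class PreprocessConfig:
    """Preprocessing and quantification parameters.

    Defaults follow the study protocol: mastoid-average reference, 30 Hz
    low-pass, downsampling to 250 Hz, 0.5 Hz high-pass, +-80 uV rejection in
    200 ms sliding windows, epochs [-200, 1250) ms, baseline [-200, 0) ms,
    MMR window [300, 600) ms on the anterior ROI (F3, Fz, F4).  Filter and
    resampling stages can be disabled (``None``) for analytic round-trip
    checks.  All time grids are half-open.
    """

    lowpass_hz: float | None = 30.0
    highpass_hz: float | None = 0.5
    resample_hz: float | None = 250.0
    reject_threshold_uv: float = 80.0
    reject_window_ms: float = 200.0
    reject_mode: str = "absolute"  # or "peak_to_peak" (> 2*threshold per window)
    epoch_window_ms: tuple[float, float] = (-200.0, 1250.0)
    baseline_window_ms: tuple[float, float] = (-200.0, 0.0)
    mmr_window_ms: tuple[float, float] = (300.0, 600.0)
    roi: tuple[str, ...] = ("F3", "Fz", "F4")
    reference_labels: tuple[str, str] = ("A1", "A2")
    contrast: str = "pooled"  # or "matched" (same-syllable deviant - standard)

    def __post_init__(self):
        e0, e1 = self.epoch_window_ms
        for name, (w0, w1) in (("baseline", self.baseline_window_ms),
                               ("mmr", self.mmr_window_ms)):
            if not (e0 <= w0 < w1 <= e1):
                raise ValueError(f"{name} window must lie inside the epoch window")
        if self.reject_mode not in ("absolute", "peak_to_peak"):
            raise ValueError(f"unknown reject_mode {self.reject_mode!r}")
        if self.contrast not in ("pooled", "matched"):
            raise ValueError(f"unknown contrast {self.contrast!r}")


@dataclass
class EpochSet:
    """Per-trial baseline-corrected epochs (trials x channels x time)."""

    data: np.ndarray
    times_ms: np.ndarray
    channel_labels: list[str]
    condition: np.ndarray  # "standard" / "deviant" per trial
    syllable: np.ndarray
    valid: np.ndarray  # bool per trial
    excluded_reason: np.ndarray  # str per trial; "none" iff valid
    fs_hz: float

    def __post_init__(self):
        n = self.data.shape[0]
        for arr in (self.condition, self.syllable, self.valid, self.excluded_reason):
            if len(arr) != n:
                raise ValueError("per-trial metadata length mismatch")
        if not np.all(self.valid == (self.excluded_reason == REASON_NONE)):
            raise ValueError("valid flags inconsistent with excluded_reason")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def exclusion_fraction(self, condition: str) -> float:
        """Fraction of this condition's trials flagged invalid for artifacts.

        Edge-truncated and deviant-adjacent standards are design exclusions
        and are not counted in the artifact-exclusion rate.
        """
        mask = self.condition == condition
        eligible = mask & (self.excluded_reason != REASON_EDGE) \
                        & (self.excluded_reason != REASON_STANDARD_AFTER_DEVIANT)
        if eligible.sum() == 0:
            return float("nan")
        return float((self.excluded_reason[eligible] == REASON_ARTIFACT).mean())


@dataclass
class DifferenceWave:
    """Per-subject deviant-minus-standard average (channels x time)."""

    data: np.ndarray
    times_ms: np.ndarray
    channel_labels: list[str]
    subject_id: str = ""
    n_valid_deviant: int = 0
    n_valid_standard: int = 0
    exclusion_fractions: dict = field(default_factory=dict)


@dataclass(frozen=True)
class MMRMeasure:
    """Scalar late-MMR endophenotype for one subject (ROI window mean, uV)."""

    subject_id: str
    mmr_uv: float
    n_valid_deviant: int
    n_valid_standard: int
    exclusion_fraction_deviant: float
    exclusion_fraction_standard: float

    def __post_init__(self):
        if not np.isfinite(self.mmr_uv):
            raise ValueError("mmr_uv must be finite")
        if self.n_valid_deviant < 1 or self.n_valid_standard < 1:
            raise ValueError("need >= 1 valid trial per condition for a defined MMR")
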