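"""Synthetic continuous EEG with embedded condition-dependent ERPs.

Each simulated recording is pink-noise background plus, at every stimulus
onset, a common auditory evoked response; deviant trials additionally carry
the subject's deviant-minus-standard difference component on the frontal
channels (F3, Fz, F4).  That difference component is the sum of

* a group waveform — controls: two negativities near 200 ms and ~400-550 ms;
  poor spellers: a positivity of up to ~5 uV between 200 and 600 ms,
* a genetic term — per risk allele of each causal SNP, an additive shift of
  the 300-600 ms window mean, realized as a unit boxcar over that window,
* a subject-level random offset over the same window (between-subject
  variability of the late MMR).

A configurable fraction of trials receives a +-150 uV boxcar artifact so
that the +-80 uV rejection criterion must fire; ground-truth contaminated
trial indices are returned for recall checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..erp.containers import ContinuousEEG
from .seeds import STREAM_EEG, child_seed
from .stimuli import DEVIANT, StimulusSequence, generate_stimulus_block

#: default per-risk-allele shifts of the late-MMR window mean (uV/allele),
#: magnitudes of the order reported for the associated candidate SNPs
DEFAULT_ALLELE_SHIFTS_UV = {
    "rs17819126": 3.0,
    "rs8053211": -1.8,
    "rs2875891": -1.5,
    "rs3743204": -1.7,
    "rs16973771": -1.4,
    "rs11100040": 1.6,
}

DEFAULT_MONTAGE = ("F3", "Fz", "F4", "Cz", "Pz", "A1", "A2")
FRONTAL_ROI = ("F3", "Fz", "F4")


def _gauss(t_ms: np.ndarray, center: float, width: float, amp: float) -> np.ndarray:
    return amp * np.exp(-0.5 * ((t_ms - center) / width) ** 2)


@dataclass(frozen=True)
class ERPTemplateModel:
    """Waveform and noise model for the simulated oddball EEG.

    Amplitudes in uV, times in ms.  ``per_allele_shift_uv`` maps causal SNP
    rsIDs to the additive change of the 300-600 ms window mean per risk
    allele; ``subject_sigma_uv`` is the SD of the subject-level random offset
    of that window mean.  ``noise_sigma_uv`` is the per-channel SD of the
    1/f^alpha background.  ``artifact_rate`` is the fraction of trials given
    a high-amplitude transient.
    """

    control_amp_uv: float = 1.5
    poor_amp_uv: float = 4.5
    per_allele_shift_uv: dict = field(default_factory=lambda: dict(DEFAULT_ALLELE_SHIFTS_UV))
    shift_window_ms: tuple[float, float] = (300.0, 600.0)
    subject_sigma_uv: float = 4.0
    noise_sigma_uv: float = 8.0
    noise_exponent: float = 1.0
    alpha_amp_uv: float = 1.0
    artifact_rate: float = 0.2
    artifact_amp_uv: float = 150.0
    artifact_duration_ms: tuple[float, float] = (200.0, 400.0)

    def __post_init__(self):
        if not 0.0 <= self.artifact_rate < 1.0:
            raise ValueError(f"artifact_rate must be in [0, 1), got {self.artifact_rate}")

    def common_response(self, t_ms: np.ndarray) -> np.ndarray:
        """Obligatory auditory response added at every stimulus onset."""
        return _gauss(t_ms, 100.0, 30.0, -2.0) + _gauss(t_ms, 220.0, 50.0, 1.2)

    def group_difference(self, t_ms: np.ndarray, poor_speller: bool) -> np.ndarray:
        """Group-level deviant-minus-standard component."""
        if poor_speller:
            w = np.zeros_like(t_ms)
            inside = (t_ms >= 200.0) & (t_ms <= 600.0)
            w[inside] = self.poor_amp_uv * np.sin(np.pi * (t_ms[inside] - 200.0) / 400.0) ** 2
            return w
        return (_gauss(t_ms, 200.0, 45.0, -self.control_amp_uv)
                + _gauss(t_ms, 480.0, 90.0, -self.control_amp_uv))

    def window_boxcar(self, t_ms: np.ndarray) -> np.ndarray:
        """Unit boxcar over the shift window: window mean exactly 1 uV."""
        lo, hi = self.shift_window_ms
        return ((t_ms >= lo) & (t_ms < hi)).astype(float)

    def difference_template(self, t_ms: np.ndarray, poor_speller: bool,
                            offset_uv: float) -> np.ndarray:
        """Full difference component; ``offset_uv`` = genetic + subject term."""
        return self.group_difference(t_ms, poor_speller) + offset_uv * self.window_boxcar(t_ms)

    def genetic_offset(self, dosages: pd.Series) -> float:
        """Sum of per-allele shifts weighted by risk-allele dosage (missing -> 0)."""
        total = 0.0
        for rsid, shift in self.per_allele_shift_uv.items():
            if rsid in dosages.index:
                d = dosages[rsid]
                if np.isfinite(d):
                    total += shift * float(d)
        return total


@dataclass
class SimulatedRecording:
    """One subject x block continuous recording plus ground truth."""

    subject_id: str
    block_id: int
    eeg: ContinuousEEG
    events: pd.DataFrame
    artifact_trials: np.ndarray  # indices of trials given an injected artifact


def _pink_noise(rng: np.random.Generator, n_channels: int, n_samples: int,
                fs_hz: float, exponent: float, sigma: float,
                alpha_amp: float) -> np.ndarray:
    """1/f^exponent noise per channel, scaled to SD ``sigma``, plus optional
    10 Hz rhythm with random phase per channel."""
    if sigma == 0 and alpha_amp == 0:
        return np.zeros((n_channels, n_samples))
    out = np.zeros((n_channels, n_samples))
    if sigma > 0:
        freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs_hz)
        scale = np.ones_like(freqs)
        scale[1:] = freqs[1:] ** (-exponent / 2.0)
        scale[0] = 0.0
        spec = (rng.standard_normal((n_channels, len(freqs)))
                + 1j * rng.standard_normal((n_channels, len(freqs)))) * scale
        noise = np.fft.irfft(spec, n=n_samples, axis=1)
        sd = noise.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        out += sigma * noise / sd
    if alpha_amp > 0:
        t = np.arange(n_samples) / fs_hz
        phases = rng.uniform(0, 2 * np.pi, size=n_channels)
        out += alpha_amp * np.sin(2 * np.pi * 10.0 * t[None, :] + phases[:, None])
    return out


def simulate_block_recording(sequence: StimulusSequence, model: ERPTemplateModel,
                             poor_speller: bool, offset_uv: float,
                             montage: tuple[str, ...] = DEFAULT_MONTAGE,
                             fs_hz: float = 500.0,
                             seed: int | np.random.SeedSequence = 0,
                             subject_id: str = "S001") -> SimulatedRecording:
    """Render one stimulus block to a continuous recording."""
    missing = {"A1", "A2", *FRONTAL_ROI} - set(montage)
    if missing:
        raise ValueError(f"montage lacks required channels: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    n_ch = len(montage)
    onsets = sequence.trials["onset_ms"].to_numpy()
    duration_ms = onsets[-1] + 1500.0
    n_samples = int(round(duration_ms / 1000.0 * fs_hz))
    frontal_idx = [montage.index(ch) for ch in FRONTAL_ROI]
    scalp_idx = [i for i, ch in enumerate(montage) if ch not in ("A1", "A2")]

    data = _pink_noise(rng, n_ch, n_samples, fs_hz, model.noise_exponent,
                       model.noise_sigma_uv, model.alpha_amp_uv)

    # ERP templates on a 0-800 ms support grid (compact: no overlap between
    # one trial's response and the next trial's epoch at ISI >= 1450 ms)
    tmpl_t = np.arange(0.0, 800.0, 1000.0 / fs_hz)
    common = model.common_response(tmpl_t)
    diff = model.difference_template(tmpl_t, poor_speller, offset_uv)
    is_deviant = (sequence.trials["condition"] == DEVIANT).to_numpy()
    for onset, dev in zip(onsets, is_deviant):
        i0 = int(round(onset / 1000.0 * fs_hz))
        i1 = min(i0 + len(tmpl_t), n_samples)
        seg = slice(i0, i1)
        k = i1 - i0
        for ch in scalp_idx:
            data[ch, seg] += common[:k]
        if dev:
            for ch in frontal_idx:
                data[ch, seg] += diff[:k]

    # artifact transients: +-150 uV boxcars guaranteed inside the epoch window
    n_trials = len(onsets)
    contaminated = np.flatnonzero(rng.random(n_trials) < model.artifact_rate)
    for tr in contaminated:
        dur = rng.uniform(*model.artifact_duration_ms)
        start = onsets[tr] + rng.uniform(0.0, 800.0)
        i0 = int(round(start / 1000.0 * fs_hz))
        i1 = min(i0 + int(round(dur / 1000.0 * fs_hz)), n_samples)
        ch = rng.integers(0, len(scalp_idx))
        sign = 1.0 if rng.random() < 0.5 else -1.0
        data[scalp_idx[ch], i0:i1] += sign * model.artifact_amp_uv

    eeg = ContinuousEEG(samples=data, fs_hz=fs_hz, channel_labels=list(montage),
                        reference_label="Cz")
    return SimulatedRecording(subject_id=subject_id, block_id=sequence.block_id,
                              eeg=eeg, events=sequence.to_events(),
                              artifact_trials=contaminated)


def generate_eeg_dataset(genotypes: pd.DataFrame, phenotypes: pd.DataFrame,
                         model: ERPTemplateModel = ERPTemplateModel(),
                         blocks: tuple[int, ...] = (1, 2),
                         montage: tuple[str, ...] = DEFAULT_MONTAGE,
                         fs_hz: float = 500.0,
                         n_total: int = 600, n_deviant: int = 90,
                         min_spacing: int = 2,
                         isi_range_ms: tuple[float, float] = (1450.0, 1750.0),
                         seed: int = 0) -> dict[str, list[SimulatedRecording]]:
    """Simulate the full study: per subject, one recording per block.

    The per-subject difference component is the group waveform (by
    poor-speller status) plus the genetic window-mean offset implied by the
    subject's dosages and a subject-level Gaussian offset.  Stimulus
    sequences are drawn independently per subject and block.
    """
    dataset: dict[str, list[SimulatedRecording]] = {}
    for s_idx, subject in enumerate(phenotypes.index):
        poor = bool(phenotypes.loc[subject, "poor_speller"])
        offset = model.genetic_offset(genotypes.loc[subject])
        if model.subject_sigma_uv > 0:
            subj_rng = np.random.default_rng(child_seed(seed, STREAM_EEG, s_idx, 0))
            offset += model.subject_sigma_uv * subj_rng.standard_normal()
        recs = []
        for block in blocks:
            seq = generate_stimulus_block(
                block, n_total=n_total, n_deviant=n_deviant,
                min_spacing=min_spacing, isi_range_ms=isi_range_ms,
                seed=child_seed(seed, STREAM_EEG, s_idx, block, 1))
            recs.append(simulate_block_recording(
                seq, model, poor, offset, montage=montage, fs_hz=fs_hz,
                seed=child_seed(seed, STREAM_EEG, s_idx, block, 2),
                subject_id=str(subject)))
        dataset[str(subject)] = recs
    return dataset
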