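"""Epoching, design exclusions, artifact rejection and MMR quantification."""

import numpy as np
import pandas as pd
import pytest

from mmrkit.erp.containers import (REASON_STANDARD_AFTER_DEVIANT,
                                   ContinuousEEG, DifferenceWave,
                                   MMRMeasure, PreprocessConfig)
from mmrkit.erp.epochs import (average_and_difference, compare_exclusion_rates,
                               epoch, mmr_amplitude, reject_artifacts)

LABELS = ["F3", "Fz", "F4", "A1", "A2"]


def make_eeg(data, fs=250.0):
    return ContinuousEEG(samples=data, fs_hz=fs, channel_labels=list(LABELS))


def make_events(onsets_ms, conditions, syllables=None):
    return pd.DataFrame({
        "onset_ms": onsets_ms,
        "condition": conditions,
        "syllable": syllables if syllables is not None else ["pa"] * len(onsets_ms),
    })


def test_epoch_grid_has_363_samples_at_250hz():
    # half-open [-200, 1250) at 4 ms: oracle by direct grid construction
    oracle = np.arange(-200.0, 1250.0, 4.0)
    eeg = make_eeg(np.zeros((5, 2000)))
    eps = epoch(eeg, make_events([2000.0], ["deviant"]))
    assert eps.data.shape[2] == len(oracle) == 363
    assert np.allclose(eps.times_ms, oracle)


def test_constant_channel_zeroed_by_baseline_correction():
    data = np.full((5, 2000), 5.0)
    eps = epoch(make_eeg(data), make_events([2000.0], ["standard"]))
    assert np.allclose(eps.data, 0.0)


def test_standard_after_deviant_flagged_by_scan_oracle(rng):
    conditions = rng.choice(["standard", "deviant"], size=40, p=[0.8, 0.2])
    onsets = 1000.0 + 2000.0 * np.arange(40)
    eeg = make_eeg(np.zeros((5, int(40 * 2000 * 0.25) + 2000)))
    eps = epoch(eeg, make_events(onsets, conditions))
    # independent scan oracle over the event list
    expected = [i for i in range(1, 40)
                if conditions[i] == "standard" and conditions[i - 1] == "deviant"]
    flagged = list(np.flatnonzero(eps.excluded_reason == REASON_STANDARD_AFTER_DEVIANT))
    assert flagged == expected


def test_event_at_recording_edge_flagged_not_crashed():
    eeg = make_eeg(np.zeros((5, 500)))
    eps = epoch(eeg, make_events([40.0, 1000.0], ["standard", "standard"]))
    assert not eps.valid[0]          # needs 200 ms before onset
    assert not eps.valid[1]          # runs past the end
    assert (eps.excluded_reason == "edge").all()


class TestRejection:
    def make_epochs(self, peak_uv, n_samples=10):
        data = np.zeros((5, 3000))
        data[0, 600] = peak_uv  # inside the first epoch, after onset
        eps = epoch(make_eeg(data), make_events([2000.0], ["deviant"]))
        return eps

    def test_all_zero_epoch_valid(self):
        eps = reject_artifacts(self.make_epochs(0.0))
        assert eps.valid.all()

    def test_single_100uv_sample_invalid(self):
        eps = reject_artifacts(self.make_epochs(100.0))
        assert not eps.valid[0]
        assert eps.excluded_reason[0] == "artifact"

    def test_uniform_79uv_valid_at_boundary(self):
        data = np.full((5, 3000), 79.0)
        eps = epoch(make_eeg(data), make_events([2000.0], ["deviant"]))
        # baseline correction removes the offset entirely -> well below 80
        eps = reject_artifacts(eps)
        assert eps.valid.all()

    def test_peak_to_peak_mode_uses_window_range(self):
        cfg = PreprocessConfig(reject_mode="peak_to_peak")
        # 100 uV swing within one window: range 200 > 160 -> invalid
        data = np.zeros((5, 3000))
        data[0, 600] = 100.0
        data[0, 610] = -100.0
        eps = reject_artifacts(epoch(make_eeg(data), make_events([2000.0], ["deviant"]), cfg), cfg)
        assert not eps.valid[0]
        # same extremes 600 ms apart exceed no single 200 ms window
        data2 = np.zeros((5, 3000))
        data2[0, 550] = 100.0
        data2[0, 700] = -100.0
        eps2 = reject_artifacts(epoch(make_eeg(data2), make_events([2000.0], ["deviant"]), cfg), cfg)
        assert eps2.valid[0]


class TestDifferenceAndMMR:
    def build(self, deviant_bump=0.0, n_trials=12):
        fs = 250.0
        step = 2000.0
        onsets = 1000.0 + step * np.arange(n_trials)
        conditions = ["deviant" if i % 4 == 0 else "standard" for i in range(n_trials)]
        data = np.zeros((5, int((onsets[-1] + 1500) * fs / 1000)))
        for onset, cond in zip(onsets, conditions):
            if cond == "deviant" and deviant_bump:
                i0 = int(round((onset + 300.0) / 1000 * fs))
                i1 = int(round((onset + 600.0) / 1000 * fs))
                data[:3, i0:i1] += deviant_bump
        eps = epoch(make_eeg(data), make_events(onsets, conditions))
        return reject_artifacts(eps)

    def test_identical_waveforms_give_zero_difference(self):
        diff = average_and_difference(self.build(0.0))
        assert np.allclose(diff.data, 0.0)

    def test_injected_offset_recovered_exactly(self):
        diff = average_and_difference(self.build(5.0))
        m = mmr_amplitude(diff)
        assert m.mmr_uv == pytest.approx(5.0, abs=1e-12)

    def test_stochastic_average_matches_naive_loop_oracle(self, rng):
        eps = self.build(0.0)
        eps.data[:] = rng.standard_normal(eps.data.shape)
        diff = average_and_difference(eps)
        dev = [eps.data[i] for i in range(eps.n_trials)
               if eps.valid[i] and eps.condition[i] == "deviant"]
        std = [eps.data[i] for i in range(eps.n_trials)
               if eps.valid[i] and eps.condition[i] == "standard"]
        oracle = sum(dev) / len(dev) - sum(std) / len(std)
        assert np.allclose(diff.data, oracle, atol=1e-12)

    def test_empty_condition_raises(self):
        eps = self.build(0.0)
        eps.condition[:] = "standard"
        with pytest.raises(ValueError, match="deviant"):
            average_and_difference(eps)


class TestMMRAmplitude:
    def make_diff(self, data, fs=250.0):
        times = np.arange(-200.0, 1250.0, 1000.0 / fs)
        return DifferenceWave(data=data, times_ms=times, channel_labels=list(LABELS),
                              subject_id="s", n_valid_deviant=10, n_valid_standard=40)

    def test_constant_two_uv(self):
        times = np.arange(-200.0, 1250.0, 4.0)
        diff = self.make_diff(np.full((5, len(times)), 2.0))
        assert mmr_amplitude(diff).mmr_uv == pytest.approx(2.0)

    def test_linear_ramp_mean_matches_grid_oracle(self):
        times = np.arange(-200.0, 1250.0, 4.0)
        data = np.zeros((5, len(times)))
        mask = (times >= 300) & (times < 600)
        ramp = (times[mask] - 300.0) / 300.0  # 0 -> 1 uV across the window
        data[:, mask] = ramp
        expected = ramp.mean()  # analytic mean on the 4 ms grid
        assert mmr_amplitude(self.make_diff(data)).mmr_uv == pytest.approx(expected)
        assert expected == pytest.approx(0.5, abs=1.0 / 150)  # half-grid correction

    def test_roi_channels_averaged(self):
        times = np.arange(-200.0, 1250.0, 4.0)
        data = np.zeros((5, len(times)))
        data[0], data[1], data[2] = 1.0, 2.0, 3.0
        assert mmr_amplitude(self.make_diff(data)).mmr_uv == pytest.approx(2.0)

    def test_missing_roi_channel_raises(self):
        times = np.arange(-200.0, 1250.0, 4.0)
        diff = DifferenceWave(data=np.zeros((2, len(times))), times_ms=times,
                              channel_labels=["A1", "A2"], subject_id="s",
                              n_valid_deviant=1, n_valid_standard=1)
        with pytest.raises(KeyError, match="ROI"):
            mmr_amplitude(diff)


def measure(subject, f_std, f_dev):
    return MMRMeasure(subject_id=subject, mmr_uv=0.0, n_valid_deviant=5,
                      n_valid_standard=5, exclusion_fraction_deviant=f_dev,
                      exclusion_fraction_standard=f_std)


class TestExclusionRates:
    def test_identical_fractions_give_null_result(self):
        ms = [measure(f"s{i}", 0.2, 0.2) for i in range(4)]
        t, p = compare_exclusion_rates(ms)
        assert t == 0.0 and p == 1.0

    def test_matches_hand_computed_paired_t(self):
        std, dev = [0.1, 0.2, 0.3], [0.3, 0.2, 0.1]
        ms = [measure(f"s{i}", s, d) for i, (s, d) in enumerate(zip(std, dev))]
        t, p = compare_exclusion_rates(ms)
        d = np.array(std) - np.array(dev)  # closed-form paired t on 3 pairs
        t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(3))
        assert t == pytest.approx(t_hand)
        from scipy import stats
        assert p == pytest.approx(2 * stats.t.sf(abs(t_hand), df=2))

    def test_constant_nonzero_difference_warns_degenerate(self):
        ms = [measure(f"s{i}", 0.3, 0.1) for i in range(3)]
        with pytest.warns(UserWarning, match="degenerate"):
            t, p = compare_exclusion_rates(ms)
        assert p == 0.0

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError, match="2 subjects"):
            compare_exclusion_rates([measure("s0", 0.1, 0.1)])
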