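"""Area detector semantics, bilateral gating, pre-detection spectra."""

import numpy as np
import pytest

import nacloop as nl
from nacloop.detector import (
    Detection,
    DetectorConfig,
    bilateral_gate,
    detect_channel,
    long_term_trend,
    pre_detection_spectrum,
    short_term_auc,
)
from nacloop.io import LFPRecord

FS = 250.0


def brute_force_detect(x, fs, config):
    """Window-materializing reference implementation of the area detector."""
    from scipy.signal import butter, sosfiltfilt

    x = np.asarray(x, dtype=float)
    if config.detector_band_hz is not None:
        sos = butter(4, config.detector_band_hz, btype="bandpass", fs=fs, output="sos")
        x = sosfiltfilt(sos, x)
    n_st = int(round(config.st_window_s * fs))
    capacity = int(round(config.lt_window_s / config.st_window_s))
    st = [np.mean(np.abs(x[i * n_st:(i + 1) * n_st])) for i in range(x.size // n_st)]
    fired = []
    last_fire = -np.inf
    for i, value in enumerate(st):
        history = st[max(0, i - capacity):i]
        t_end = (i + 1) * config.st_window_s
        if len(history) >= config.min_history_windows and (t_end - last_fire) > config.refractory_s:
            lt = config.fixed_lt if config.fixed_lt is not None else np.mean(history)
            if lt > 0 and value > lt * (1 + config.threshold_pct / 100.0):
                fired.append(i)
                last_fire = t_end
    return fired


def step_signal(level_before, level_after, before_s=120.0, after_s=2.0):
    n1 = int(before_s * FS)
    n2 = int(after_s * FS)
    return np.concatenate([np.full(n1, level_before), np.full(n2, level_after)])


RAW = DetectorConfig(detector_band_hz=None, threshold_pct=100.0)


class TestShortTermAUC:
    def test_constant_window(self):
        assert short_term_auc(np.ones(500), FS) == pytest.approx(1.0)

    def test_sinusoid_mean_rectified(self):
        t = np.arange(500) / FS
        x = 3.0 * np.sin(2 * np.pi * 5.0 * t)  # integer cycles in 2 s
        assert short_term_auc(x, FS) == pytest.approx(2 * 3.0 / np.pi, rel=0.01)

    def test_zero_window(self):
        assert short_term_auc(np.zeros(500), FS) == 0.0

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            short_term_auc(np.ones(400), FS)


class TestLongTermTrend:
    def test_constant_history(self):
        assert long_term_trend([2.5] * 10) == pytest.approx(2.5)

    def test_trailing_mean(self):
        assert long_term_trend([1, 1, 1, 1, 5]) == pytest.approx(1.8)

    def test_warmup_uses_available_values(self):
        assert long_term_trend([3.0]) == pytest.approx(3.0)

    def test_empty_history_not_armed(self):
        with pytest.raises(ValueError):
            long_term_trend([])


class TestDetectChannel:
    def test_constant_signal_never_fires(self):
        x = np.ones(int(300 * FS))
        assert detect_channel(x, FS, RAW) == []

    def test_step_above_threshold_fires_once(self):
        x = step_signal(1.0, 2.1)
        dets = detect_channel(x, FS, RAW)
        assert len(dets) == 1
        assert dets[0].window_index == 60  # the step window
        assert dets[0].st_auc == pytest.approx(2.1)
        assert dets[0].lt_auc == pytest.approx(1.0)
        assert dets[0].excess_pct == pytest.approx(110.0)

    def test_step_below_threshold_silent(self):
        assert detect_channel(step_signal(1.0, 1.9), FS, RAW) == []

    def test_matches_brute_force_on_random_signals(self, rng):
        config = DetectorConfig(detector_band_hz=None, threshold_pct=63.0)
        for _ in range(25):
            x = np.abs(rng.standard_normal(int(120 * FS)))
            x *= 1.0 + 2.0 * (rng.random(x.size) < 0.01).cumsum() % 2
            fired = [d.window_index for d in detect_channel(x, FS, config)]
            assert fired == brute_force_detect(x, FS, config)

    def test_scale_invariance(self, rng):
        x = np.abs(rng.standard_normal(int(240 * FS))) + 0.1
        config = DetectorConfig(detector_band_hz=None, threshold_pct=63.0)
        base = [d.window_index for d in detect_channel(x, FS, config)]
        for c in (0.01, 5.0, 1000.0):
            assert [d.window_index for d in detect_channel(c * x, FS, config)] == base

    def test_refractory_spacing(self, rng):
        x = np.abs(rng.standard_normal(int(600 * FS))) * (
            1.0 + 5.0 * (np.arange(int(600 * FS)) % int(4 * FS) < int(2 * FS)))
        config = DetectorConfig(detector_band_hz=None, threshold_pct=63.0,
                                refractory_s=10.0)
        times = [d.time_s for d in detect_channel(x, FS, config)]
        assert len(times) > 1
        assert np.all(np.diff(times) > 10.0)

    def test_blanked_windows_neither_fire_nor_enter_trend(self):
        x = step_signal(1.0, 2.1)
        mask = np.zeros(x.size, dtype=bool)
        mask[int(120 * FS):] = True  # blank the step window
        config = DetectorConfig(detector_band_hz=None, threshold_pct=100.0)
        assert detect_channel(x, FS, config, blank_mask=mask) == []

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            DetectorConfig(st_window_s=120.0, lt_window_s=2.0)
        with pytest.raises(ValueError):
            DetectorConfig(threshold_pct=0.0)


def det(side, idx):
    return Detection(side, idx, (idx + 1) * 2.0, 1.0, 0.4)


class TestBilateralGate:
    def test_left_only_gives_nothing(self):
        config = DetectorConfig()
        assert bilateral_gate([det("left", 3)], [], config) == []

    def test_same_window_pairs(self):
        config = DetectorConfig()
        out = bilateral_gate([det("left", 3)], [det("right", 3)], config)
        assert len(out) == 1 and out[0].side == "bilateral"
        assert out[0].window_index == 3

    def test_tolerance_window(self):
        tight = DetectorConfig(coincidence_tolerance_windows=0)
        loose = DetectorConfig(coincidence_tolerance_windows=1)
        left, right = [det("left", 3)], [det("right", 4)]
        assert bilateral_gate(left, right, tight) == []
        assert len(bilateral_gate(left, right, loose)) == 1

    def test_each_detection_consumed_once(self):
        config = DetectorConfig(coincidence_tolerance_windows=1)
        out = bilateral_gate([det("left", 3), det("left", 4)], [det("right", 4)], config)
        assert len(out) == 1


class TestPreDetectionSpectrum:
    def _rec_with_burst(self, rng, mode="burst"):
        n = int(400 * FS)
        t = np.arange(n) / FS
        data = 0.5 * rng.standard_normal((2, n))
        if mode == "burst":
            window = (t >= 296.0) & (t < 300.0)
            data[:, window] += 8.0 * np.sin(2 * np.pi * 4.0 * t[window])
        elif mode == "silence":  # near-silent pre-detection seconds
            data[:, (t >= 295.0) & (t < 300.0)] *= 0.01
        return LFPRecord(samples=data, fs_hz=FS,
                         channel_roles=("left_ventral", "right_ventral"))

    def test_burst_triggered_detection_flagged(self, rng):
        rec = self._rec_with_burst(rng)
        detection = Detection("bilateral", 149, 300.0, 1.0, 0.3)
        out = pre_detection_spectrum(rec, [detection])
        assert out.fraction_elevated == 1.0
        assert bool(out.table["elevated"].iloc[0]) is True

    def test_silence_before_detection_not_flagged(self, rng):
        rec = self._rec_with_burst(rng, mode="silence")
        detection = Detection("bilateral", 149, 300.0, 1.0, 0.3)
        out = pre_detection_spectrum(rec, [detection])
        assert bool(out.table["elevated"].iloc[0]) is False

    def test_no_detections_reported_absent(self, rng):
        out = pre_detection_spectrum(self._rec_with_burst(rng), [])
        assert out.fraction_elevated is None and len(out.table) == 0

    def test_detection_too_close_to_start_dropped(self, rng):
        rec = self._rec_with_burst(rng)
        early = Detection("bilateral", 1, 4.0, 1.0, 0.3)
        out = pre_detection_spectrum(rec, [early])
        assert out.n_dropped == 1 and len(out.table) == 0
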