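"""Synthetic-data generator: scheduling, determinism, spectral contracts."""

from datetime import datetime

import numpy as np
import pytest
from scipy import stats as sps

import nacloop as nl
from nacloop.clock import hour_intervals
from nacloop.events import BehavioralEvent, EventLog
from nacloop.spectral import psd, psd_band_power


def daytime_config(**kw):
    kw.setdefault("duration_s", 36000.0)
    kw.setdefault("start_clock", datetime(2021, 1, 1, 7, 0))
    kw.setdefault("channels", ("left_ventral",))
    return nl.SimulationConfig(**kw)


class TestScheduling:
    def test_zero_rates_give_empty_log(self):
        config = daytime_config(event_rates={"magnet_craving": 0.0})
        assert len(nl.schedule_events(config)) == 0

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            daytime_config(event_rates={"magnet_craving": -1.0})

    def test_poisson_counts_match_rate(self):
        # 2/h over a 10-h awake window: pooled count over 100 seeds should
        # sit inside the 99% interval of Poisson(100 * expected)
        expected_one = 2.0 * (36000.0 - 2 * 62.0) / 3600.0
        total = sum(
            len(nl.schedule_events(daytime_config(
                event_rates={"magnet_craving": 2.0}, rng_seed=seed)))
            for seed in range(100)
        )
        lo, hi = sps.poisson.ppf([0.005, 0.995], 100 * expected_one)
        assert lo <= total <= hi

    def test_same_seed_identical_logs(self):
        config = daytime_config(event_rates={"magnet_craving": 3.0}, rng_seed=7)
        a = nl.schedule_events(config)
        b = nl.schedule_events(config)
        assert [(e.time_s, e.kind) for e in a] == [(e.time_s, e.kind) for e in b]
        assert len(a) > 0

    def test_events_respect_circadian_gating(self):
        config = nl.SimulationConfig(duration_s=86400.0, rng_seed=2,
                                     channels=("left_ventral",))
        log = nl.schedule_events(config)
        sleep = hour_intervals(config.start_clock, config.duration_s, 22, 7)
        def asleep(t):
            return any(a <= t < b for a, b in sleep)
        for e in log:
            assert 0.0 < e.time_s < config.duration_s
            if e.kind == "scheduled_sleep":
                assert asleep(e.time_s)
            else:
                assert not asleep(e.time_s)

    def test_ratings_in_likert_range(self):
        config = daytime_config(
            event_rates={"magnet_craving": 3.0, "magnet_hunger": 3.0}, rng_seed=3
        )
        log = nl.schedule_events(config)
        assert len(log) > 0
        for e in log:
            for r in (e.loc_rating, e.craving_rating, e.hunger_rating):
                assert r is None or 1 <= r <= 5


class TestRecording:
    def test_bit_identical_given_seed(self):
        config = daytime_config(duration_s=120.0,
                                event_rates={"bite_loc": 30.0}, rng_seed=4,
                                event_margin_s=6.0)
        rec_a, log_a = nl.simulate(config)
        rec_b, log_b = nl.simulate(config)
        assert np.array_equal(rec_a.samples, rec_b.samples)
        assert [e.time_s for e in log_a] == [e.time_s for e in log_b]

    def test_event_outside_duration_rejected(self):
        config = daytime_config(duration_s=60.0)
        log = EventLog([BehavioralEvent(120.0, "bite_loc")])
        with pytest.raises(ValueError):
            nl.generate_recording(config, log)

    def test_background_slope_recovered(self):
        # averaged periodogram over 2-40 Hz recovers -beta within +/-0.3
        beta = 1.5
        densities = []
        for seed in range(50):
            config = daytime_config(duration_s=60.0, event_rates={}, rng_seed=seed,
                                    background_exponent=beta,
                                    sleep_delta_amplitude_uv=0.0)
            rec = nl.generate_recording(config, EventLog([]))
            f, p = psd(rec.channel("left_ventral"), config.fs_hz, nperseg_s=4.0)
            densities.append(p)
        mean_p = np.mean(densities, axis=0)
        mask = (f >= 2.0) & (f <= 40.0)
        slope = np.polyfit(np.log10(f[mask]), np.log10(mean_p[mask]), 1)[0]
        assert abs(slope + beta) < 0.3

    def test_burst_amplitude_monotone_in_band_power(self):
        elevations = []
        for amp in (0.0, 6.0, 12.0):
            config = nl.SimulationConfig.buffet(
                duration_s=600.0, rng_seed=5, channels=("left_ventral",),
                burst_amplitude_uv=amp)
            rec, log = nl.simulate(config)
            table = nl.buffet_analysis(rec, log, bands=("low_frequency",))
            elevations.append(float(table["mean_loc_db"].iloc[0]))
        assert elevations[0] < elevations[1] < elevations[2]

    def test_left_only_laterality_leaves_right_channel_untouched(self):
        kw = dict(duration_s=300.0, rng_seed=6, channels=nl.VENTRAL_ROLES)
        silent = nl.SimulationConfig.buffet(burst_amplitude_uv=0.0, **kw)
        left_only = nl.SimulationConfig.buffet(burst_laterality="left_only", **kw)
        log = nl.schedule_events(silent)  # same seed -> same schedule
        rec_silent = nl.generate_recording(silent, log)
        rec_left = nl.generate_recording(left_only, log)
        assert np.array_equal(rec_left.channel("right_ventral"),
                              rec_silent.channel("right_ventral"))
        assert not np.array_equal(rec_left.channel("left_ventral"),
                                  rec_silent.channel("left_ventral"))

    def test_zero_amplitude_is_null(self):
        # with silent bursts, LOC and standard pre-bite low-frequency power
        # are indistinguishable when pooled across seeds
        diffs = []
        for seed in range(50):
            config = nl.SimulationConfig.buffet(
                duration_s=300.0, rng_seed=seed, channels=("left_ventral",),
                burst_amplitude_uv=0.0,
                event_rates={"bite_loc": 120.0, "bite_standard": 120.0})
            rec, log = nl.simulate(config)
            try:
                table = nl.buffet_analysis(rec, log, bands=("low_frequency",))
            except ValueError:  # a seed with <2 epochs in one condition
                continue
            diffs.append(float(table["mean_loc_db"].iloc[0]
                               - table["mean_standard_db"].iloc[0]))
        assert len(diffs) >= 40
        assert sps.ttest_1samp(diffs, 0.0).pvalue > 0.01

    def test_single_burst_band_power_localized_and_quadratic(self):
        # one burst on a silent background: band power lives in the burst
        # window only, and scales with the square of the amplitude
        def burst_band_power(amp):
            config = daytime_config(duration_s=120.0, background_scale_uv=0.0,
                                    sleep_delta_amplitude_uv=0.0,
                                    burst_band_hz=(4.0, 6.0), burst_amplitude_uv=amp,
                                    burst_lead_s=2.0, event_rates={})
            log = EventLog([BehavioralEvent(60.0, "bite_loc")])
            rec = nl.generate_recording(config, log)
            x = rec.channel("left_ventral")
            fs = config.fs_hz
            burst = x[int(58.0 * fs):int(60.0 * fs)]
            silent = x[int(20.0 * fs):int(22.0 * fs)]
            f, p_burst = psd(burst, fs)
            _, p_silent = psd(silent, fs)
            return (psd_band_power(f, p_burst, (2, 8)),
                    psd_band_power(f, p_silent, (2, 8)))

        in_burst, in_silence = burst_band_power(5.0)
        assert in_burst > 50 * (in_silence + 1e-12)
        doubled, _ = burst_band_power(10.0)
        # same seed -> identical burst waveform, so the ratio is exactly 4
        assert doubled == pytest.approx(4.0 * in_burst, rel=1e-9)

    def test_sleep_delta_present_during_sleep_hours(self):
        config = nl.SimulationConfig(duration_s=10 * 3600.0, rng_seed=8,
                                     channels=("left_ventral",), event_rates={})
        rec = nl.generate_recording(config, EventLog([]))
        fs = config.fs_hz
        asleep = rec.channel("left_ventral")[int(2 * 3600 * fs):int(3 * 3600 * fs)]
        awake = rec.channel("left_ventral")[int(8 * 3600 * fs):int(9 * 3600 * fs)]
        f_s, p_s = psd(asleep, fs)
        f_a, p_a = psd(awake, fs)
        assert psd_band_power(f_s, p_s, "delta") > 5 * psd_band_power(f_a, p_a, "delta")


class TestConfigValidation:
    @pytest.mark.parametrize("kw", [
        {"fs_hz": 100.0},
        {"burst_band_hz": (8.0, 2.0)},
        {"burst_band_hz": (0.5, 8.0)},
        {"burst_laterality": "both"},
        {"channels": ("left_ventral", "nose")},
        {"duration_s": -1.0},
    ])
    def test_invalid_config_rejected(self, kw):
        with pytest.raises(ValueError):
            nl.SimulationConfig(**kw)
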