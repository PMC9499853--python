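"""Synthetic LFP generator.

Produces labeled multichannel recordings with the statistical structure the
downstream analyses assume, so the whole pipeline is testable without access
to patient data:

* per-channel 1/f^beta background activity (filtered Gaussian noise with a
  testable log-log spectral slope);
* transient band-limited low-frequency bursts (default 2-8 Hz) ending at
  craving-magnet swipes and loss-of-control bites — amplitude-modulated
  narrowband noise rather than a pure sinusoid, so band-power estimators are
  exercised on realistic bandwidth;
* sustained high-amplitude delta during configured sleep hours;
* a circadian day structure anchored to a wall-clock start time, with
  behavioral events confined to awake (or, for scheduled sleep snapshots,
  sleep) hours.

Amplitudes are in microvolts but are arbitrary in absolute terms; only
ratios (burst vs. background, sleep delta vs. background) matter to the
analyses, and the defaults are chosen so that pre-event band-power
elevations land in the few-dB range reported for this class of recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import datetime

import numpy as np
from scipy import signal

from .clock import hour_intervals
from .events import EVENT_KINDS, SLEEP_KINDS, BehavioralEvent, EventLog
from .io import CHANNEL_ROLES, LFPRecord

_LATERALITIES = ("bilateral", "left_only", "right_only")


@dataclass
class SimulationConfig:
    """All knobs of the synthetic recording.

    The defaults describe one simulated ambulatory day: four bipolar
    channels at 250 Hz, 1/f^1.5 background, craving-locked 2-8 Hz bursts,
    sleep 22:00-07:00 with sustained delta, recording starting at local
    midnight.
    """

    duration_s: float = 86400.0
    fs_hz: float = 250.0
    channels: tuple[str, ...] = CHANNEL_ROLES
    background_exponent: float = 1.5
    background_scale_uv: float = 10.0
    #: events/hour of *eligible* (awake or sleep) time, per kind
    event_rates: dict[str, float] = field(
        default_factory=lambda: {
            "magnet_craving": 1.0,
            "magnet_hunger": 1.0,
            "magnet_control": 1.0,
            "scheduled_awake": 1.0,
            "scheduled_sleep": 1.0,
        }
    )
    burst_band_hz: tuple[float, float] = (2.0, 8.0)
    #: 1/f^tilt slope inside the burst band: bursts are delta-dominant,
    #: matching the low-frequency character of the biomarker
    burst_spectral_tilt: float = 2.5
    burst_amplitude_uv: float = 12.0
    hunger_burst_amplitude_uv: float = 0.0
    burst_lead_s: float = 30.0
    burst_laterality: str = "bilateral"
    sleep_start_hour: float = 22.0
    sleep_end_hour: float = 7.0
    sleep_delta_amplitude_uv: float = 25.0
    sleep_delta_band_hz: tuple[float, float] = (1.0, 4.0)
    sleep_ramp_s: float = 30.0
    start_clock: datetime = field(default_factory=lambda: datetime(2021, 1, 1, 0, 0))
    snapshot_len_s: float = 180.0
    #: keep events this far from the recording edges so pre-event windows fit
    event_margin_s: float = 62.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.fs_hz <= 180.0:
            raise ValueError("fs_hz must exceed 180 (twice the 90 Hz ceiling)")
        lo, hi = self.burst_band_hz
        if not (1.0 <= lo < hi <= 90.0):
            raise ValueError("burst_band_hz must satisfy 1 <= low < high <= 90")
        if self.burst_laterality not in _LATERALITIES:
            raise ValueError(f"burst_laterality must be one of {_LATERALITIES}")
        unknown = set(self.event_rates) - EVENT_KINDS
        if unknown:
            raise ValueError(f"unknown event kinds in rates: {sorted(unknown)}")
        for kind, rate in self.event_rates.items():
            if not np.isfinite(rate) or rate < 0:
                raise ValueError(f"rate for {kind!r} must be finite and >= 0")
        unknown_ch = set(self.channels) - set(CHANNEL_ROLES)
        if unknown_ch:
            raise ValueError(f"unknown channel roles: {sorted(unknown_ch)}")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")

    # -- profiles ---------------------------------------------------------

    @classmethod
    def buffet(cls, duration_s: float = 1800.0, rng_seed: int = 0, **kw) -> "SimulationConfig":
        """In-lab multi-item-buffet session profile.

        A short daytime recording with video-annotated bites: LOC bites
        carry a 2 s pre-bite low-frequency burst, standard-meal bites do
        not.  Bite rates default to 30/hour each, giving per-condition
        group sizes in the mid teens for a half-hour session, the scale of
        an in-lab meal assessment.
        """
        kw.setdefault("event_rates", {"bite_loc": 30.0, "bite_standard": 30.0})
        kw.setdefault("burst_lead_s", 2.0)
        kw.setdefault("event_margin_s", 6.0)
        kw.setdefault("start_clock", datetime(2021, 1, 1, 12, 0))
        return cls(duration_s=duration_s, rng_seed=rng_seed, **kw)

    @classmethod
    def ambulatory(cls, duration_s: float = 86400.0, rng_seed: int = 0, **kw) -> "SimulationConfig":
        """One simulated ambulatory day (the class defaults, spelled out)."""
        return cls(duration_s=duration_s, rng_seed=rng_seed, **kw)

    def with_seed(self, rng_seed: int) -> "SimulationConfig":
        return replace(self, rng_seed=rng_seed)


def _rng(seed: int, stream: int, *extra: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream, *extra]))


def _eligible_intervals(config: SimulationConfig, kind: str) -> list[tuple[float, float]]:
    """Recording-time intervals where events of ``kind`` may occur."""
    m = config.event_margin_s
    if kind in SLEEP_KINDS:
        raw = hour_intervals(
            config.start_clock, config.duration_s,
            config.sleep_start_hour, config.sleep_end_hour,
        )
    else:
        raw = hour_intervals(
            config.start_clock, config.duration_s,
            config.sleep_end_hour, config.sleep_start_hour,
        )
    out = []
    for a, b in raw:
        a, b = max(a, m), min(b, config.duration_s - m)
        if b > a:
            out.append((a, b))
    return out


_RATING_PROFILES = {
    # (loc, craving, hunger): per-kind Likert sampling ranges (inclusive)
    "bite_loc": ((4, 5), (4, 5), (1, 3)),
    "bite_standard": ((1, 2), (1, 2), (2, 4)),
    "magnet_craving": ((4, 5), (4, 5), (1, 2)),
    "magnet_hunger": ((1, 2), (1, 3), (4, 5)),
    "magnet_control": ((1, 1), (1, 2), (1, 2)),
    "scheduled_awake": (None, None, None),
    "scheduled_sleep": (None, None, None),
}


def schedule_events(config: SimulationConfig) -> EventLog:
    """Draw a Poisson event schedule for every configured event kind.

    Counts are Poisson with mean rate x eligible hours; times are uniform
    over the eligible (awake or sleep) intervals, kept ``event_margin_s``
    clear of the recording edges.  Deterministic given ``rng_seed``.
    """
    rng = _rng(config.rng_seed, 0)
    events: list[BehavioralEvent] = []
    for kind in sorted(config.event_rates):
        rate = config.event_rates[kind]
        if rate == 0:
            continue
        intervals = _eligible_intervals(config, kind)
        lengths = np.array([b - a for a, b in intervals])
        total_s = lengths.sum()
        if total_s <= 0:
            continue
        n = rng.poisson(rate * total_s / 3600.0)
        u = rng.uniform(0.0, total_s, size=n)
        starts = np.concatenate([[0.0], np.cumsum(lengths)])[:-1]
        idx = np.searchsorted(np.cumsum(lengths), u, side="right")
        times = np.array([intervals[i][0] + (u[j] - starts[i]) for j, i in enumerate(idx)])
        loc_r, crav_r, hung_r = _RATING_PROFILES[kind]

        def draw(rng_range):
            if rng_range is None:
                return None
            return int(rng.integers(rng_range[0], rng_range[1] + 1))

        for t in np.sort(times):
            events.append(
                BehavioralEvent(
                    time_s=float(t),
                    kind=kind,
                    loc_rating=draw(loc_r),
                    craving_rating=draw(crav_r),
                    hunger_rating=draw(hung_r),
                )
            )
    events.sort(key=lambda e: e.time_s)
    return EventLog(events)


# -- signal synthesis -----------------------------------------------------


def _one_over_f(
    n: int,
    beta: float,
    scale: float,
    rng: np.random.Generator,
    fs: float = 250.0,
    f_floor_hz: float = 1.0,
) -> np.ndarray:
    """Gaussian noise with power spectrum proportional to f^-beta, RMS=scale.

    The spectrum flattens below ``f_floor_hz`` (as physiological spectra
    do), which keeps the total variance finite and the in-band amplitude
    independent of recording duration.
    """
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = np.maximum(f, f_floor_hz) ** (-beta / 2.0)
    shaping[0] = 0.0
    x = np.fft.irfft(spec * shaping, n=n)
    sd = x.std()
    if sd > 0:
        x *= scale / sd
    return x


def _narrowband_noise(
    n: int,
    band: tuple[float, float],
    fs: float,
    rng: np.random.Generator,
    tilt: float = 0.0,
    order: int = 4,
) -> np.ndarray:
    """Unit-RMS bandpassed noise (4th-order zero-phase Butterworth).

    ``tilt`` applies a 1/f^tilt spectral slope inside the band, so bursts
    can be delta-dominant rather than spectrally flat.
    """
    pad = max(int(fs), n // 4)
    m = n + 2 * pad
    white = rng.standard_normal(m)
    if tilt != 0.0:
        spec = np.fft.rfft(white)
        f = np.fft.rfftfreq(m, d=1.0 / fs)
        shaping = np.zeros_like(f)
        shaping[1:] = f[1:] ** (-tilt / 2.0)
        white = np.fft.irfft(spec * shaping, n=m)
    sos = signal.butter(order, band, btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, white)[pad : pad + n]
    sd = x.std()
    if sd > 0:
        x = x / sd
    return x


def _sustained_oscillation(
    n: int, band: tuple[float, float], fs: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-RMS constant-envelope oscillation wandering inside a band.

    Narrowband noise with its Hilbert envelope normalized away: the phase
    (hence instantaneous frequency) keeps the band's character but the
    amplitude stays constant, emulating the sustained large-amplitude
    delta of slow-wave sleep rather than waxing-waning noise.
    """
    core = _narrowband_noise(n, band, fs, rng)
    phase = np.angle(signal.hilbert(core))
    return np.sqrt(2.0) * np.cos(phase)


def _burst_channels(config: SimulationConfig) -> list[str]:
    sides = {
        "bilateral": ("left_ventral", "right_ventral"),
        "left_only": ("left_ventral",),
        "right_only": ("right_ventral",),
    }[config.burst_laterality]
    return [role for role in sides if role in config.channels]


def generate_recording(config: SimulationConfig, log: EventLog) -> LFPRecord:
    """Synthesize the multichannel LFP for a given event schedule.

    Each channel gets an independent 1/f^beta background.  Craving-magnet
    and LOC-bite events receive a raised-cosine-enveloped burst of
    band-limited noise occupying ``[time - burst_lead_s, time]`` on the
    configured ventral channel(s); hunger events optionally receive a
    reduced-amplitude burst.  Sleep hours carry a sustained constant-
    envelope delta oscillation on every channel, ramped on and off.  Bit-reproducible given the
    config's ``rng_seed``.
    """
    fs = config.fs_hz
    n = int(round(config.duration_s * fs))
    for e in log:
        if not 0.0 < e.time_s < config.duration_s:
            raise ValueError(f"event at {e.time_s}s outside recording")
    if not config.channels:
        raise ValueError("no channels configured")

    data = np.empty((len(config.channels), n))
    for i, role in enumerate(config.channels):
        ch_rng = _rng(config.rng_seed, 1, CHANNEL_ROLES.index(role))
        data[i] = _one_over_f(
            n, config.background_exponent, config.background_scale_uv, ch_rng
        )

    # event-locked bursts on the biomarker (ventral) channels
    burst_rng = _rng(config.rng_seed, 2)
    burst_roles = _burst_channels(config)
    amp_by_kind = {
        "magnet_craving": config.burst_amplitude_uv,
        "bite_loc": config.burst_amplitude_uv,
        "magnet_hunger": config.hunger_burst_amplitude_uv,
    }
    for e in log:
        amp = amp_by_kind.get(e.kind, 0.0)
        # draw even when the burst is silent so schedules with zero
        # amplitude remain sample-aligned with their nonzero counterparts
        if e.kind not in amp_by_kind:
            continue
        b = int(round(e.time_s * fs))
        a = max(0, b - int(round(config.burst_lead_s * fs)))
        m = b - a
        if m < 8:
            continue
        envelope = np.hanning(m)
        for role in burst_roles:
            core = _narrowband_noise(
                m, config.burst_band_hz, fs, burst_rng,
                tilt=config.burst_spectral_tilt, order=8,
            )
            if amp > 0:
                data[config.channels.index(role), a:b] += amp * envelope * core

    # sustained sleep delta on all channels
    if config.sleep_delta_amplitude_uv > 0:
        sleep_rng = _rng(config.rng_seed, 3)
        sleep_ints = hour_intervals(
            config.start_clock, config.duration_s,
            config.sleep_start_hour, config.sleep_end_hour,
        )
        for a_s, b_s in sleep_ints:
            a, b = int(round(a_s * fs)), int(round(b_s * fs))
            m = b - a
            if m < 8:
                continue
            ramp = min(int(round(config.sleep_ramp_s * fs)), m // 2)
            envelope = np.ones(m)
            if ramp > 0:
                up = 0.5 * (1 - np.cos(np.pi * np.arange(ramp) / ramp))
                envelope[:ramp] = up
                envelope[-ramp:] = up[::-1]
            for i in range(len(config.channels)):
                core = _sustained_oscillation(m, config.sleep_delta_band_hz, fs, sleep_rng)
                data[i, a:b] += config.sleep_delta_amplitude_uv * envelope * core

    return LFPRecord(
        samples=data,
        fs_hz=fs,
        channel_roles=tuple(config.channels),
        start_clock=config.start_clock,
    )


def simulate(config: SimulationConfig) -> tuple[LFPRecord, EventLog]:
    """Schedule events and synthesize the recording in one call."""
    log = schedule_events(config)
    return generate_recording(config, log), log
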