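"""Time-frequency and spectral estimation.

The quantitative core of the analyses: a Morlet-wavelet time-frequency
transform with canonical-band averaging, decibel change relative to a
baseline, and Welch power spectral density estimation.

Canonical bands follow the clinical convention used for these recordings:
delta 2-4, theta 4-8, alpha 8-12, beta 13-30, gamma 31-50, high-gamma
50-90 Hz, plus the combined delta-theta "low-frequency" biomarker band
2-8 Hz.  Band edges are inclusive on the 1-Hz analysis grid, so the
low-frequency average equals the direct 2-8 Hz average over the delta and
theta bins.

Morlet normalization is amplitude-calibrated: a pure sinusoid of amplitude
A at a grid frequency yields power A^2/2 (its variance) at that frequency
bin, making band power directly comparable to bandpassed-variance
estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

#: Canonical frequency bands (Hz, inclusive edges on the analysis grid).
CANONICAL_BANDS: dict[str, tuple[float, float]] = {
    "delta": (2.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (13.0, 30.0),
    "gamma": (31.0, 50.0),
    "high_gamma": (50.0, 90.0),
    "low_frequency": (2.0, 8.0),
}

#: Bands reported in the standard per-band battery (biomarker band last).
BAND_ORDER = ("delta", "theta", "alpha", "beta", "gamma", "high_gamma", "low_frequency")


def default_freq_grid(low: float = 1.0, high: float = 90.0, step: float = 1.0) -> np.ndarray:
    """The analysis frequency grid, 1-90 Hz in 1-Hz steps by default."""
    return np.arange(low, high + step / 2, step)


@dataclass
class TFPower:
    """Time-frequency power: shape (n_freqs, n_times), non-negative, uV^2.

    ``edge_margin_s[i]`` is the half-wavelet length at ``freqs[i]``; power
    within that margin of either end of the epoch is contaminated by the
    reflection padding and is excluded from band averages by default.
    """

    freqs: np.ndarray
    times: np.ndarray
    power: np.ndarray
    edge_margin_s: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.edge_margin_s is None:
            self.edge_margin_s = np.zeros_like(np.asarray(self.freqs, float))


def _morlet(freq: float, fs: float, n_cycles: float) -> np.ndarray:
    """Complex Morlet wavelet, truncated at 3.5 sigma_t, amplitude-calibrated."""
    sigma_t = n_cycles / (2.0 * np.pi * freq)
    half = int(np.ceil(3.5 * sigma_t * fs))
    t = np.arange(-half, half + 1) / fs
    envelope = np.exp(-(t**2) / (2.0 * sigma_t**2))
    wave = envelope * np.exp(2j * np.pi * freq * t)
    # calibrate: unit sinusoid at `freq` -> |response|^2 == 1/2 (its variance)
    return wave * (np.sqrt(2.0) / envelope.sum())


def resolve_cycles(freqs: np.ndarray, n_cycles: float | np.ndarray | None) -> np.ndarray:
    """Per-frequency cycle counts; ``None`` selects the adaptive default.

    The default ``max(5, f/2)`` keeps 5 cycles through the low-frequency
    band and caps the spectral bandwidth at roughly 2 Hz above 10 Hz, so
    narrowband low-frequency activity is not smeared into beta and above.
    """
    freqs = np.asarray(freqs, dtype=np.float64)
    if n_cycles is None:
        return np.maximum(5.0, freqs / 2.0)
    return np.broadcast_to(np.asarray(n_cycles, dtype=np.float64), freqs.shape).copy()


def tf_power(
    x: np.ndarray,
    fs: float,
    freqs: np.ndarray | None = None,
    n_cycles: float | np.ndarray | None = None,
) -> TFPower:
    """Morlet-wavelet power of a single-channel segment.

    Power is the squared magnitude of the complex Morlet convolution at
    each (frequency, time), so scaling the input by c scales power by c^2
    exactly.  The segment is reflection-padded by the
    longest half-wavelet so every output sample sees a full convolution;
    the contaminated outer margins are flagged per frequency via
    ``edge_margin_s``.  ``n_cycles`` may be a scalar, a per-frequency
    array, or ``None`` for the adaptive default (see
    :func:`resolve_cycles`).
    """
    x = np.asarray(x, dtype=np.float64)
    if freqs is None:
        freqs = default_freq_grid()
    freqs = np.asarray(freqs, dtype=np.float64)
    if freqs.size == 0:
        raise ValueError("frequency grid is empty")
    if freqs.max() >= fs / 2.0:
        raise ValueError("max frequency must be below Nyquist")
    n = x.size
    cycles = resolve_cycles(freqs, n_cycles)
    wavelets = [_morlet(f, fs, c) for f, c in zip(freqs, cycles)]
    halves = np.array([w.size // 2 for w in wavelets])
    pad = int(halves.max())
    if pad >= n:
        raise ValueError(
            f"epoch of {n} samples too short for the lowest frequency "
            f"{freqs.min():g} Hz at {n_cycles} cycles"
        )
    xp = np.pad(x, pad, mode="reflect")
    power = np.empty((freqs.size, n))
    for i, w in enumerate(wavelets):
        conv = signal.fftconvolve(xp, w, mode="same")[pad : pad + n]
        power[i] = np.abs(conv) ** 2
    return TFPower(
        freqs=freqs,
        times=np.arange(n) / fs,
        power=power,
        edge_margin_s=halves / fs,
    )


def band_average(
    tf: TFPower,
    band: str | tuple[float, float],
    time_window_s: tuple[float, float] | None = None,
    exclude_edges: bool = True,
) -> float:
    """Mean linear power over a band's grid frequencies and a time window.

    For each in-band frequency the time average runs over the requested
    window minus (by default) that frequency's contaminated edge margin;
    the band value is the unweighted mean over in-band frequencies.
    """
    if isinstance(band, str):
        try:
            lo, hi = CANONICAL_BANDS[band]
        except KeyError:
            raise ValueError(f"unknown band {band!r}") from None
    else:
        lo, hi = band
    sel = np.flatnonzero((tf.freqs >= lo) & (tf.freqs <= hi))
    if sel.size == 0:
        raise ValueError(f"no grid frequency falls in band ({lo}, {hi}) Hz")
    if time_window_s is None:
        t0, t1 = tf.times[0], tf.times[-1]
    else:
        t0, t1 = time_window_s
    per_freq = []
    for i in sel:
        lo_t, hi_t = t0, t1
        if exclude_edges:
            m = tf.edge_margin_s[i]
            lo_t = max(lo_t, tf.times[0] + m)
            hi_t = min(hi_t, tf.times[-1] - m)
        mask = (tf.times >= lo_t) & (tf.times <= hi_t)
        if mask.any():
            per_freq.append(tf.power[i, mask].mean())
    if not per_freq:
        raise ValueError("no uncontaminated samples in the requested window")
    return float(np.mean(per_freq))


def db_change(power: float | np.ndarray, baseline: float) -> float | np.ndarray:
    """Decibel change of linear power relative to a positive baseline."""
    if baseline <= 0:
        raise ValueError("baseline power must be positive")
    return 10.0 * np.log10(np.asarray(power) / baseline)


def psd(
    x: np.ndarray,
    fs: float,
    nperseg_s: float = 2.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Welch one-sided power spectral density (units^2 per Hz).

    Hann-windowed segments of ``nperseg_s`` seconds with 50% overlap; the
    integral of the density over frequency approximates the segment
    variance (Parseval).  Raises if the segment is shorter than one Welch
    window.
    """
    x = np.asarray(x, dtype=np.float64)
    nperseg = int(round(nperseg_s * fs))
    if x.size < nperseg:
        raise ValueError(
            f"segment of {x.size} samples shorter than one Welch window ({nperseg})"
        )
    return signal.welch(x, fs=fs, window="hann", nperseg=nperseg)


def psd_band_power(
    freqs: np.ndarray, density: np.ndarray, band: str | tuple[float, float]
) -> float:
    """Mean spectral density over a band (the ambulatory per-event metric)."""
    if isinstance(band, str):
        lo, hi = CANONICAL_BANDS[band]
    else:
        lo, hi = band
    mask = (freqs >= lo) & (freqs <= hi)
    if not mask.any():
        raise ValueError(f"no PSD frequency falls in band ({lo}, {hi}) Hz")
    return float(density[mask].mean())
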