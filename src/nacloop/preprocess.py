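"""Signal cleaning and event-locked epoching.

The cleaning chain mirrors standard intracranial practice for this device
class: linear detrend, zero-phase notch filters at the mains frequency and
its harmonics below Nyquist, then a 1-90 Hz zero-phase bandpass.  Epoching
is event-locked with half-open ``[start, end)`` windows in samples; events
whose window runs off either edge of the recording are dropped and counted,
never zero-padded, to avoid biasing spectral estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
from scipy import signal

from .events import EVENT_KINDS, BehavioralEvent, EventLog
from .io import LFPRecord


def clean(
    rec: LFPRecord,
    band_hz: tuple[float, float] = (1.0, 90.0),
    notch_hz: float = 60.0,
    notch_q: float = 30.0,
) -> LFPRecord:
    """Detrend, notch-filter, and bandpass a recording, zero-phase.

    Steps, per channel: (1) remove the linear trend; (2) IIR notch at
    ``notch_hz`` and every harmonic below Nyquist (quality factor
    ``notch_q``); (3) 4th-order Butterworth bandpass over ``band_hz``.
    All filters are applied forward-backward so event latencies are not
    shifted.
    """
    fs = rec.fs_hz
    nyq = fs / 2.0
    lo, hi = band_hz
    if hi >= nyq:
        raise ValueError(f"bandpass corner {hi} Hz not below Nyquist {nyq} Hz")
    x = signal.detrend(rec.samples, axis=1, type="linear")
    f = notch_hz
    while f < nyq:
        b, a = signal.iirnotch(f, notch_q, fs=fs)
        x = signal.filtfilt(b, a, x, axis=1)
        f += notch_hz
    sos = signal.butter(4, (lo, hi), btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, x, axis=1)
    return LFPRecord(
        samples=x,
        fs_hz=fs,
        channel_roles=rec.channel_roles,
        start_clock=rec.start_clock,
        units=rec.units,
    )


@dataclass
class Epoch:
    """One event-locked window of one channel.

    ``window_s`` is (start, end) in seconds relative to the event time; the
    sample window is half-open, so an epoch with window (-2, 0) ends at the
    event sample, exclusive.
    """

    event: BehavioralEvent
    channel: str
    window_s: tuple[float, float]
    samples: np.ndarray
    fs_hz: float

    @property
    def kind(self) -> str:
        return self.event.kind

    @property
    def start_s(self) -> float:
        """Absolute start time of the window in recording seconds."""
        return self.event.time_s + self.window_s[0]

    @property
    def end_s(self) -> float:
        return self.event.time_s + self.window_s[1]

    def with_window(self, window_s: tuple[float, float], samples: np.ndarray) -> "Epoch":
        return replace(self, window_s=window_s, samples=samples)


@dataclass
class EpochSet:
    """Epochs plus a drop report from edge and stimulation-overlap exclusion."""

    epochs: list[Epoch]
    n_dropped_edge: int = 0
    n_dropped_stim: int = 0

    def __len__(self) -> int:
        return len(self.epochs)

    def __iter__(self) -> Iterator[Epoch]:
        return iter(self.epochs)

    def of_kind(self, kind: str) -> list[Epoch]:
        return [e for e in self.epochs if e.kind == kind]

    def of_channel(self, channel: str) -> list[Epoch]:
        return [e for e in self.epochs if e.channel == channel]


def epoch_events(
    rec: LFPRecord,
    log: EventLog,
    kinds: Iterable[str],
    window_s: tuple[float, float],
    channels: Optional[Sequence[str]] = None,
) -> EpochSet:
    """Extract one epoch per (event of the requested kinds x channel).

    The window is relative to the event time and half-open in samples:
    ``n = round((end - start) * fs)`` samples ending at
    ``round((t + end) * fs)``.  Events whose window does not fit inside the
    recording are dropped and counted in ``n_dropped_edge``.
    """
    start, end = window_s
    if start >= end:
        raise ValueError("window start must precede end")
    kinds = {kinds} if isinstance(kinds, str) else set(kinds)
    unknown = kinds - EVENT_KINDS
    if unknown:
        raise ValueError(f"unknown event kinds: {sorted(unknown)}")
    if channels is None:
        channels = rec.channel_roles
    fs = rec.fs_hz
    n_win = int(round((end - start) * fs))
    epochs: list[Epoch] = []
    dropped = 0
    for event in log.of_kind(kinds):
        b = int(round((event.time_s + end) * fs))
        a = b - n_win
        if a < 0 or b > rec.n_samples:
            dropped += 1
            continue
        for ch in channels:
            epochs.append(
                Epoch(
                    event=event,
                    channel=ch,
                    window_s=(start, end),
                    samples=rec.channel(ch)[a:b].copy(),
                    fs_hz=fs,
                )
            )
    return EpochSet(epochs, n_dropped_edge=dropped)


def exclude_stim_overlap(
    epochs: EpochSet | list[Epoch],
    stims: Sequence,
    guard_s: float = 0.0,
) -> EpochSet:
    """Drop epochs overlapping any stimulation bout (plus a guard margin).

    Data recorded during stimulation carry high-frequency artifact and are
    excluded from every analysis.  ``stims`` is a sequence of objects with
    ``start_s`` and ``duration_s`` attributes.
    """
    if isinstance(epochs, EpochSet):
        items = epochs.epochs
        edge = epochs.n_dropped_edge
    else:
        items = list(epochs)
        edge = 0
    intervals = [
        (s.start_s - guard_s, s.start_s + s.duration_s + guard_s) for s in stims
    ]
    kept: list[Epoch] = []
    removed = 0
    for ep in items:
        if any(ep.start_s < b and a < ep.end_s for a, b in intervals):
            removed += 1
        else:
            kept.append(ep)
    return EpochSet(kept, n_dropped_edge=edge, n_dropped_stim=removed)
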