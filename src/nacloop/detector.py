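"""The area (AUC) detector with bilateral coincidence gating.

The responsive device takes a signal area-under-the-curve measurement every
short-term window (2 s) and compares it with the average of measurements
from the trailing long-term window (2 min).  A detection is made when the
short-term value exceeds the long-term trend by a programmed percentage
(programmed in the 63-100% range clinically).  Because sustained sleep delta inflates the
long-term trend, brief awake bursts stand out while sleep activity largely
does not — that adaptivity is the point of the design.

AUC is operationalized here as the mean rectified amplitude of the
(optionally detector-band filtered) window: the area under the rectified
trace per unit time.  It is non-negative and scale-equivariant, which makes
the detector scale-invariant.  Stimulation delivery additionally requires
left and right detections to coincide (within a configurable window
tolerance), reflecting the bilateral character of the biomarker.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .io import LFPRecord, VENTRAL_ROLES
from .spectral import psd, psd_band_power


@dataclass
class DetectorConfig:
    """Closed-loop detector parameters.

    ``threshold_pct`` is the percent excess of the short-term AUC over the
    long-term trend required to fire; the clinically programmed range is 63-100%.  With
    ``fixed_lt`` set, the adaptive long-term trend is replaced by a
    constant reference (used to demonstrate that adaptation is what
    suppresses sleep detections).
    """

    enabled: bool = True
    st_window_s: float = 2.0
    lt_window_s: float = 120.0
    threshold_pct: float = 63.0
    detector_band_hz: Optional[tuple[float, float]] = (2.0, 8.0)
    require_bilateral: bool = True
    coincidence_tolerance_windows: int = 0
    refractory_s: float = 0.0
    min_history_windows: int = 1
    fixed_lt: Optional[float] = None

    def __post_init__(self) -> None:
        if self.st_window_s >= self.lt_window_s:
            raise ValueError("short-term window must be shorter than long-term")
        if self.threshold_pct <= 0:
            raise ValueError("threshold_pct must be positive")
        if self.min_history_windows < 1:
            raise ValueError("min_history_windows must be >= 1")

    @property
    def lt_capacity(self) -> int:
        """Number of short-term values covered by the long-term window."""
        return int(round(self.lt_window_s / self.st_window_s))


@dataclass(frozen=True)
class Detection:
    """One detector firing (or a gated bilateral coincidence)."""

    side: str  # left | right | bilateral
    window_index: int
    time_s: float  # end time of the triggering short-term window
    st_auc: float
    lt_auc: float

    @property
    def excess_pct(self) -> float:
        return 100.0 * (self.st_auc / self.lt_auc - 1.0)


def short_term_auc(window: np.ndarray, fs: float, st_window_s: float = 2.0) -> float:
    """Mean rectified amplitude of one short-term window.

    The window must contain exactly ``st_window_s * fs`` samples; any
    detector-band filtering happens upstream so this stays a pure window
    statistic.
    """
    window = np.asarray(window, dtype=np.float64)
    expected = int(round(st_window_s * fs))
    if window.size != expected:
        raise ValueError(f"expected {expected} samples, got {window.size}")
    return float(np.abs(window).mean())


def long_term_trend(history: Sequence[float]) -> float:
    """Arithmetic mean of the trailing short-term AUC values.

    The caller supplies only the values inside the long-term window that
    were not stimulation-blanked; during warm-up fewer values than the
    window capacity are averaged.  An empty history means the detector is
    not yet armed.
    """
    if len(history) == 0:
        raise ValueError("empty history: detector not armed")
    return float(np.mean(np.asarray(history, dtype=np.float64)))


def _band_filter(x: np.ndarray, fs: float, band: tuple[float, float]) -> np.ndarray:
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x)


def st_auc_series(
    x: np.ndarray,
    fs: float,
    config: DetectorConfig,
    blank_mask: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Short-term AUC per non-overlapping window, plus a blanked flag.

    Windows are aligned to the start of the recording; a trailing partial
    window is discarded.  A window is flagged blanked when any of its
    samples is masked (stimulation artifact).
    """
    x = np.asarray(x, dtype=np.float64)
    n_st = int(round(config.st_window_s * fs))
    if x.size < n_st:
        raise ValueError("signal shorter than one short-term window")
    if config.detector_band_hz is not None:
        x = _band_filter(x, fs, config.detector_band_hz)
    n_win = x.size // n_st
    st = np.abs(x[: n_win * n_st]).reshape(n_win, n_st).mean(axis=1)
    if blank_mask is not None:
        blank_mask = np.asarray(blank_mask, dtype=bool)
        blanked = blank_mask[: n_win * n_st].reshape(n_win, n_st).any(axis=1)
    else:
        blanked = np.zeros(n_win, dtype=bool)
    return st, blanked


def detect_channel(
    x: np.ndarray,
    fs: float,
    config: DetectorConfig,
    side: str = "left",
    blank_mask: Optional[np.ndarray] = None,
) -> list[Detection]:
    """Run the area detector over one channel.

    Sequential non-overlapping short-term windows; a detection is emitted
    for window i when the detector is armed (enough unblanked history),
    outside any refractory period, the window itself is not blanked, and
    ``st_i > lt_i * (1 + threshold_pct/100)`` with ``lt_i`` the mean of the
    trailing unblanked short-term values (the current window excluded).
    Nothing is updated retroactively by a detection.
    """
    st, blanked = st_auc_series(x, fs, config, blank_mask)
    capacity = config.lt_capacity
    history: list[float] = []
    out: list[Detection] = []
    last_fire_t = -np.inf
    for i, (value, is_blanked) in enumerate(zip(st, blanked)):
        t_end = (i + 1) * config.st_window_s
        if not is_blanked and len(history) >= config.min_history_windows:
            lt = config.fixed_lt if config.fixed_lt is not None else float(np.mean(history))
            armed = lt > 0 and (t_end - last_fire_t) > config.refractory_s
            if armed and value > lt * (1.0 + config.threshold_pct / 100.0):
                out.append(Detection(side, i, t_end, float(value), float(lt)))
                last_fire_t = t_end
        if not is_blanked:
            history.append(float(value))
            if len(history) > capacity:
                history.pop(0)
    return out


def bilateral_gate(
    left: Sequence[Detection],
    right: Sequence[Detection],
    config: DetectorConfig,
) -> list[Detection]:
    """Pair left and right detections into bilateral coincidences.

    Detections coincide when their window indices differ by at most
    ``coincidence_tolerance_windows``; matching is greedy in time order and
    each unilateral detection is consumed at most once.  The emitted
    bilateral detection carries the later window's timing and the larger
    side's short-term AUC.
    """
    tol = config.coincidence_tolerance_windows
    out: list[Detection] = []
    j = 0
    used_right: set[int] = set()
    rights = sorted(right, key=lambda d: d.window_index)
    for ld in sorted(left, key=lambda d: d.window_index):
        while j < len(rights) and rights[j].window_index < ld.window_index - tol:
            j += 1
        for k in range(j, len(rights)):
            rd = rights[k]
            if rd.window_index > ld.window_index + tol:
                break
            if k in used_right:
                continue
            used_right.add(k)
            later = ld if ld.window_index >= rd.window_index else rd
            out.append(
                Detection(
                    side="bilateral",
                    window_index=later.window_index,
                    time_s=later.time_s,
                    st_auc=max(ld.st_auc, rd.st_auc),
                    lt_auc=later.lt_auc,
                )
            )
            break
    return out


def detect_bilateral(
    rec: LFPRecord,
    config: DetectorConfig,
    blank_mask: Optional[np.ndarray] = None,
) -> dict[str, list[Detection]]:
    """Run the detector on both ventral channels and gate bilaterally.

    Returns ``{"left": [...], "right": [...], "bilateral": [...]}``; when
    ``require_bilateral`` is off, the bilateral list is the time-merged
    union of both sides instead of the coincidence-gated pairs.
    """
    left_role, right_role = VENTRAL_ROLES
    left = detect_channel(rec.channel(left_role), rec.fs_hz, config, "left", blank_mask)
    right = detect_channel(rec.channel(right_role), rec.fs_hz, config, "right", blank_mask)
    if config.require_bilateral:
        gated = bilateral_gate(left, right, config)
    else:
        gated = sorted(left + right, key=lambda d: d.time_s)
    return {"left": left, "right": right, "bilateral": gated}


def detections_to_frame(detections: Sequence[Detection]) -> pd.DataFrame:
    rows = [
        {
            "side": d.side,
            "window_index": d.window_index,
            "time_s": d.time_s,
            "st_auc": d.st_auc,
            "lt_auc": d.lt_auc,
            "excess_pct": d.excess_pct,
        }
        for d in detections
    ]
    return pd.DataFrame(
        rows, columns=["side", "window_index", "time_s", "st_auc", "lt_auc", "excess_pct"]
    )


def hourly_counts(detections: Sequence[Detection]) -> pd.DataFrame:
    """Detections per recording hour, mirroring the device's hourly counts."""
    hours = [int(d.time_s // 3600) for d in detections]
    if not hours:
        return pd.DataFrame(columns=["hour", "count"])
    series = pd.Series(hours).value_counts().sort_index()
    return pd.DataFrame({"hour": series.index, "count": series.values})


@dataclass
class PreDetectionComparison:
    """Per-detection pre-trigger spectra vs. the long-term baseline."""

    table: pd.DataFrame  # time_s, pre_band_power, baseline_band_power, elevated
    n_dropped: int
    fraction_elevated: Optional[float]


def pre_detection_spectrum(
    rec: LFPRecord,
    detections: Sequence[Detection],
    pre_s: float = 5.0,
    baseline_window_s: float = 120.0,
    band: tuple[float, float] = (2.0, 8.0),
    channels: Sequence[str] = VENTRAL_ROLES,
) -> PreDetectionComparison:
    """Check what the detector fired on: PSD of the pre-detection seconds.

    For each detection, the Welch PSD of the ``pre_s`` seconds before the
    triggering window end is compared in the low-frequency band against the
    average over the trailing ``baseline_window_s`` baseline window; the
    detection is flagged *elevated* when the pre-trigger band density
    exceeds the baseline's (averaged over the requested channels).
    Detections without enough preceding signal are dropped and counted.
    """
    fs = rec.fs_hz
    rows = []
    dropped = 0
    for d in detections:
        end = int(round(d.time_s * fs))
        pre_a = end - int(round(pre_s * fs))
        base_a = max(0, pre_a - int(round(baseline_window_s * fs)))
        if pre_a <= 0 or pre_a - base_a < int(round(pre_s * fs)):
            dropped += 1
            continue
        pre_vals, base_vals = [], []
        for ch in channels:
            x = rec.channel(ch)
            f_pre, p_pre = psd(x[pre_a:end], fs, nperseg_s=min(pre_s, 2.0))
            f_base, p_base = psd(x[base_a:pre_a], fs, nperseg_s=min(pre_s, 2.0))
            pre_vals.append(psd_band_power(f_pre, p_pre, band))
            base_vals.append(psd_band_power(f_base, p_base, band))
        pre_power = float(np.mean(pre_vals))
        base_power = float(np.mean(base_vals))
        rows.append(
            {
                "time_s": d.time_s,
                "side": d.side,
                "pre_band_power": pre_power,
                "baseline_band_power": base_power,
                "elevated": pre_power > base_power,
            }
        )
    table = pd.DataFrame(
        rows, columns=["time_s", "side", "pre_band_power", "baseline_band_power", "elevated"]
    )
    fraction = float(table["elevated"].mean()) if len(table) else None
    return PreDetectionComparison(table=table, n_dropped=dropped, fraction_elevated=fraction)
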