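"""Statistical battery and detection-performance evaluation.

Implements the clinical comparison battery: a pooled-variance
two-sided Student's t-test for in-lab bandpower contrasts, a one-way ANOVA
with Bonferroni-corrected pairwise t-tests for the three ambulatory
conditions (control, craving, hunger), a Pearson chi-square on detection
counts, and sensitivity/specificity of detections against labeled events.
Group summaries are reported as mean +/- s.e.m. with n, matching the
field's reporting convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .events import EventLog
from .io import LFPRecord, VENTRAL_ROLES
from .preprocess import EpochSet, clean, epoch_events, exclude_stim_overlap
from .spectral import (
    BAND_ORDER,
    CANONICAL_BANDS,
    band_average,
    db_change,
    default_freq_grid,
    psd,
    psd_band_power,
    tf_power,
)


@dataclass
class StatResult:
    """One statistical comparison with its group summaries."""

    test_name: str
    statistic: float
    df: tuple[float, ...] | float
    p_value: float
    group_means: dict[str, float] = field(default_factory=dict)
    group_sems: dict[str, float] = field(default_factory=dict)
    group_ns: dict[str, int] = field(default_factory=dict)
    correction: Optional[str] = None
    posthoc: dict[str, "StatResult"] = field(default_factory=dict)

    def summary(self) -> str:
        groups = ", ".join(
            f"{k}: {self.group_means[k]:.3g} ± {self.group_sems[k]:.3g} (n={self.group_ns[k]})"
            for k in self.group_means
        )
        head = f"{self.test_name}: stat={self.statistic:.4g}, df={self.df}, p={self.p_value:.4g}"
        if self.correction:
            head += f" [{self.correction}]"
        return f"{head}; {groups}" if groups else head


def _sem(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1) / np.sqrt(len(x))) if len(x) > 1 else float("nan")


def _group_summary(result: StatResult, **groups: np.ndarray) -> StatResult:
    for name, values in groups.items():
        values = np.asarray(values, dtype=np.float64)
        result.group_means[name] = float(values.mean())
        result.group_sems[name] = _sem(values)
        result.group_ns[name] = int(len(values))
    return result


def ttest_two_sided(a: Sequence[float], b: Sequence[float]) -> StatResult:
    """Classic pooled-variance two-sample Student's t-test, two-sided."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    pooled = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / (
        len(a) + len(b) - 2
    )
    if pooled == 0.0:
        if a.mean() == b.mean():
            result = StatResult("student_t", 0.0, float(len(a) + len(b) - 2), 1.0)
            return _group_summary(result, a=a, b=b)
        raise ValueError("zero pooled variance with unequal means is degenerate")
    t, p = sps.ttest_ind(a, b, equal_var=True)
    result = StatResult("student_t", float(t), float(len(a) + len(b) - 2), float(p))
    return _group_summary(result, a=a, b=b)


def anova_three(
    control: Sequence[float],
    craving: Sequence[float],
    hunger: Sequence[float],
) -> StatResult:
    """One-way ANOVA over the three ambulatory conditions, with post hoc.

    Pairwise pooled t-tests follow, Bonferroni-corrected by the fixed
    factor 3 (the three condition contrasts), capped at 1.
    """
    groups = {"control": np.asarray(control, float),
              "craving": np.asarray(craving, float),
              "hunger": np.asarray(hunger, float)}
    for name, g in groups.items():
        if len(g) < 2:
            raise ValueError(f"group {name!r} needs n >= 2")
    f, p = sps.f_oneway(*groups.values())
    n_total = sum(len(g) for g in groups.values())
    result = StatResult("one_way_anova", float(f), (2.0, float(n_total - 3)), float(p))
    _group_summary(result, **groups)
    pairs = [("craving", "control"), ("craving", "hunger"), ("hunger", "control")]
    for x, y in pairs:
        sub = ttest_two_sided(groups[x], groups[y])
        sub.p_value = min(1.0, sub.p_value * 3.0)
        sub.correction = "bonferroni_x3"
        result.posthoc[f"{x}_vs_{y}"] = sub
    result.correction = "bonferroni_x3 (posthoc)"
    return result


def chi_square_2x2(table: Sequence[Sequence[float]], correction: bool = False) -> StatResult:
    """Pearson chi-square on a 2x2 count table (no continuity correction
    by default)."""
    arr = np.asarray(table, dtype=np.float64)
    if arr.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (arr < 0).any() or arr.sum() == 0:
        raise ValueError("counts must be non-negative with a positive total")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("a zero marginal makes the test undefined")
    chi2, p, dof, _ = sps.chi2_contingency(arr, correction=correction)
    return StatResult("chi_square", float(chi2), float(dof), float(p))


@dataclass
class PerformanceResult:
    """Detection performance against labeled behavioral events."""

    sensitivity: Optional[float]
    specificity: Optional[float]
    n_positives: int
    n_hits: int
    n_detections: int
    n_unmatched_detections: int
    n_negative_windows: int


def detection_performance(
    detections: Sequence,
    log: EventLog,
    match_window_s: float = 60.0,
    positive_kinds: Sequence[str] = ("magnet_craving", "bite_loc"),
    negative_kinds: Sequence[str] = ("magnet_control", "scheduled_awake"),
) -> PerformanceResult:
    """Sensitivity and specificity of detections for labeled events.

    A positive event is a hit when at least one detection falls within
    ``match_window_s`` before it.  Sensitivity is hits/positives (absent
    when there are no positives).  Detections not matched to any positive
    count as spurious; specificity is 1 minus spurious detections per
    eligible negative window (the control-class events), floored at 0.
    """
    det_times = np.array(sorted(d.time_s for d in detections))
    positives = [e.time_s for e in log.of_kind(set(positive_kinds))]
    negatives = [e.time_s for e in log.of_kind(set(negative_kinds))]
    matched = np.zeros(det_times.size, dtype=bool)
    hits = 0
    for t in positives:
        in_window = (det_times >= t - match_window_s) & (det_times <= t)
        if in_window.any():
            hits += 1
            matched |= in_window
    n_unmatched = int((~matched).sum())
    sensitivity = hits / len(positives) if positives else None
    specificity = (
        max(0.0, 1.0 - n_unmatched / len(negatives)) if negatives else None
    )
    return PerformanceResult(
        sensitivity=sensitivity,
        specificity=specificity,
        n_positives=len(positives),
        n_hits=hits,
        n_detections=int(det_times.size),
        n_unmatched_detections=n_unmatched,
        n_negative_windows=len(negatives),
    )


# -- end-to-end analyses --------------------------------------------------


def _epoch_band_power(
    epochs: Sequence,
    bands: Sequence[str],
    fs: float,
    analysis_window_s: tuple[float, float],
    pad_s: float,
    n_cycles: float | None,
) -> pd.DataFrame:
    """Per-epoch linear band power over the analysis window.

    Epoch samples must already include ``pad_s`` of context on each side of
    the analysis window so the lowest-frequency wavelets have support.
    """
    lo = min(CANONICAL_BANDS[b][0] for b in bands)
    hi = max(CANONICAL_BANDS[b][1] for b in bands)
    freqs = default_freq_grid(max(1.0, lo), hi)
    rows = []
    for idx, ep in enumerate(epochs):
        tf = tf_power(ep.samples, fs, freqs=freqs, n_cycles=n_cycles)
        # epoch time axis starts at window_s[0]; shift the analysis window
        offset = analysis_window_s[0] - ep.window_s[0]
        window = (offset, offset + (analysis_window_s[1] - analysis_window_s[0]))
        for band in bands:
            rows.append(
                {
                    "epoch": idx,
                    "event_time_s": ep.event.time_s,
                    "kind": ep.kind,
                    "channel": ep.channel,
                    "band": band,
                    "power": band_average(tf, band, time_window_s=window),
                }
            )
    return pd.DataFrame(rows)


def buffet_analysis(
    rec: LFPRecord,
    log: EventLog,
    bands: Sequence[str] = BAND_ORDER,
    channels: Sequence[str] = ("left_ventral",),
    window_s: tuple[float, float] = (-2.0, 0.0),
    stims: Sequence = (),
    n_cycles: float | None = None,
    baseline: str = "condition_mean",
    preclean: bool = True,
) -> pd.DataFrame:
    """In-lab bite-locked band-power contrast: LOC vs. standard-meal bites.

    The 2 s preceding each bite are Morlet-transformed and averaged within
    each canonical band; per-epoch values are expressed in dB relative to
    a baseline and compared between conditions with a pooled t-test.  All
    bands are reported so the expected negative results outside the
    low-frequency band are checkable.

    ``baseline='condition_mean'`` references each channel/band to the mean
    linear power of that channel's standard-meal epochs (so standard bites
    average ~0 dB); ``baseline='epoch_pre'`` uses each epoch's own
    pre-window (the window immediately before the analysis window).  The
    choice changes absolute dB levels, not the contrast.

    Returns one row per (channel, band) with group means +/- s.e.m. in dB,
    t, df and p.
    """
    if preclean:
        rec = clean(rec)
    fs = rec.fs_hz
    lo_freq = min(CANONICAL_BANDS[b][0] for b in bands)
    from .spectral import resolve_cycles

    lo_cycles = float(resolve_cycles(np.array([lo_freq]), n_cycles)[0])
    pad_s = float(np.ceil(10 * (lo_cycles / (2 * np.pi * lo_freq) * 3.5)) / 10)
    extra = (window_s[1] - window_s[0]) if baseline == "epoch_pre" else 0.0
    wide = (window_s[0] - pad_s - extra, window_s[1] + pad_s)
    epochs = epoch_events(rec, log, {"bite_loc", "bite_standard"}, wide, channels)
    epochs = exclude_stim_overlap(epochs, stims)
    table = _epoch_band_power(epochs, bands, fs, window_s, pad_s, n_cycles)
    if table.empty:
        raise ValueError("no usable bite epochs")
    if baseline == "epoch_pre":
        pre_window = (2 * window_s[0] - window_s[1], window_s[0])
        base_table = _epoch_band_power(epochs, bands, fs, pre_window, pad_s, n_cycles)
        table = table.merge(
            base_table.rename(columns={"power": "baseline_power"})[
                ["epoch", "band", "baseline_power"]
            ],
            on=["epoch", "band"],
        )
    rows = []
    for (channel, band), sub in table.groupby(["channel", "band"], sort=False):
        loc = sub[sub["kind"] == "bite_loc"]
        std = sub[sub["kind"] == "bite_standard"]
        if len(loc) < 2 or len(std) < 2:
            raise ValueError(
                f"need >= 2 epochs per condition on {channel}/{band} "
                f"(got {len(loc)} LOC, {len(std)} standard)"
            )
        if baseline == "condition_mean":
            ref = float(std["power"].mean())
            loc_db = np.asarray(db_change(loc["power"].to_numpy(), ref))
            std_db = np.asarray(db_change(std["power"].to_numpy(), ref))
            baseline_ref = "mean standard-meal power (same channel/band)"
        elif baseline == "epoch_pre":
            loc_db = 10 * np.log10(loc["power"].to_numpy() / loc["baseline_power"].to_numpy())
            std_db = 10 * np.log10(std["power"].to_numpy() / std["baseline_power"].to_numpy())
            baseline_ref = "per-epoch pre-window power"
        else:
            raise ValueError(f"unknown baseline mode {baseline!r}")
        test = ttest_two_sided(loc_db, std_db)
        rows.append(
            {
                "channel": channel,
                "band": band,
                "mean_loc_db": float(np.mean(loc_db)),
                "sem_loc_db": _sem(loc_db),
                "n_loc": len(loc_db),
                "mean_standard_db": float(np.mean(std_db)),
                "sem_standard_db": _sem(std_db),
                "n_standard": len(std_db),
                "t": test.statistic,
                "df": test.df,
                "p": test.p_value,
                "baseline_ref": baseline_ref,
            }
        )
    return pd.DataFrame(rows)


def ambulatory_analysis(
    rec: LFPRecord,
    log: EventLog,
    band: tuple[float, float] | str = "low_frequency",
    channels: Sequence[str] = VENTRAL_ROLES,
    pre_window_s: float = 60.0,
    stims: Sequence = (),
    preclean: bool = True,
) -> dict[str, StatResult]:
    """Ambulatory pre-swipe contrast: craving vs. hunger vs. control.

    For each ventral channel, the ``pre_window_s`` seconds before each
    magnet swipe are Welch-transformed; the per-event metric is the mean
    spectral density in the biomarker band (units^2 per Hz).  The three
    condition groups then enter a one-way ANOVA with Bonferroni-corrected
    pairwise t-tests.  Returns one StatResult per channel.
    """
    if preclean:
        rec = clean(rec)
    kinds = {"magnet_craving", "magnet_hunger", "magnet_control"}
    epochs = epoch_events(rec, log, kinds, (-pre_window_s, 0.0), channels)
    epochs = exclude_stim_overlap(epochs, stims)
    results: dict[str, StatResult] = {}
    for ch in channels:
        values: dict[str, list[float]] = {k: [] for k in kinds}
        for ep in epochs.of_channel(ch):
            f, p = psd(ep.samples, rec.fs_hz)
            values[ep.kind].append(psd_band_power(f, p, band))
        if any(len(v) == 0 for v in values.values()):
            raise ValueError(f"empty condition group on channel {ch}")
        results[ch] = anova_three(
            control=values["magnet_control"],
            craving=values["magnet_craving"],
            hunger=values["magnet_hunger"],
        )
    return results
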