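"""Stimulation policy: turning gated detections into constrained bouts.

A bout is two 5-s bursts of 125 Hz stimulation (10 s total).  The policy
enforces the clinical safety constraints: delivery only during awake hours
(07:00-22:00 local), at most 700 bouts (~117 min) per local calendar day,
and no overlapping bouts — a detection arriving during an ongoing bout is
dropped, not queued.  Charge density is carried as metadata only; no
electrical model is attached to it.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime
from typing import Sequence

import numpy as np
import pandas as pd

from .clock import day_index, in_hour_range, local_time
from .detector import Detection


@dataclass
class StimulationPolicy:
    frequency_hz: float = 125.0
    bursts_per_bout: int = 2
    burst_duration_s: float = 5.0
    daily_bout_cap: int = 700
    awake_start_hour: float = 7.0
    awake_end_hour: float = 22.0
    charge_density_uc_cm2: float = 0.5
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.daily_bout_cap < 0:
            raise ValueError("daily_bout_cap must be >= 0")
        if self.bursts_per_bout < 1 or self.burst_duration_s <= 0:
            raise ValueError("bout structure must be positive")

    @property
    def bout_duration_s(self) -> float:
        return self.bursts_per_bout * self.burst_duration_s


@dataclass(frozen=True)
class StimulationEvent:
    """One delivered bout, with the detection that triggered it."""

    start_s: float
    duration_s: float
    day_index: int
    trigger: Detection


def apply_policy(
    detections: Sequence[Detection],
    policy: StimulationPolicy,
    start_clock: datetime,
) -> list[StimulationEvent]:
    """Deliver one bout per qualifying detection under the policy limits.

    Qualifying means: the policy is enabled, the detection's local time is
    inside awake hours, no bout is ongoing, and the local calendar day has
    budget left.  Detections must be time-ordered.
    """
    if not policy.enabled:
        return []
    out: list[StimulationEvent] = []
    bouts_today: dict[int, int] = {}
    current_bout_end = -np.inf
    last_t = -np.inf
    for d in detections:
        if d.time_s < last_t:
            raise ValueError("detections must be time-ordered")
        last_t = d.time_s
        when = local_time(start_clock, d.time_s)
        if not in_hour_range(when, policy.awake_start_hour, policy.awake_end_hour):
            continue
        if d.time_s < current_bout_end:
            continue
        day = day_index(start_clock, d.time_s)
        if bouts_today.get(day, 0) >= policy.daily_bout_cap:
            continue
        bouts_today[day] = bouts_today.get(day, 0) + 1
        out.append(
            StimulationEvent(
                start_s=d.time_s,
                duration_s=policy.bout_duration_s,
                day_index=day,
                trigger=d,
            )
        )
        current_bout_end = d.time_s + policy.bout_duration_s
    return out


def daily_budget_minutes(policy: StimulationPolicy, rounded: bool = True) -> float:
    """Maximum stimulated minutes per day implied by the bout cap.

    700 bouts of 10 s give 116.67 min, reported as 117 when rounded.
    """
    minutes = policy.daily_bout_cap * policy.bout_duration_s / 60.0
    return int(round(minutes)) if rounded else minutes


def blank_stim_windows(
    n_samples: int,
    fs: float,
    stims: Sequence[StimulationEvent],
    guard_s: float = 0.0,
) -> np.ndarray:
    """Per-sample boolean mask covering every bout plus guard margins.

    Consumed by epoch exclusion and by the detector's long-term trend,
    which must not average stimulation artifact.
    """
    mask = np.zeros(int(n_samples), dtype=bool)
    for s in stims:
        a = int(round((s.start_s - guard_s) * fs))
        b = int(round((s.start_s + s.duration_s + guard_s) * fs))
        mask[max(a, 0) : max(min(b, mask.size), 0)] = True
    return mask


def stims_to_frame(stims: Sequence[StimulationEvent]) -> pd.DataFrame:
    rows = [
        {
            "start_s": s.start_s,
            "duration_s": s.duration_s,
            "day_index": s.day_index,
            "trigger_side": s.trigger.side,
            "trigger_window_index": s.trigger.window_index,
        }
        for s in stims
    ]
    return pd.DataFrame(
        rows,
        columns=["start_s", "duration_s", "day_index", "trigger_side", "trigger_window_index"],
    )


def daily_summary(
    detections: Sequence[Detection],
    stims: Sequence[StimulationEvent],
    start_clock: datetime,
) -> pd.DataFrame:
    """Per-day counts of detections, bouts, and stimulated minutes."""
    det_days = pd.Series([day_index(start_clock, d.time_s) for d in detections])
    stim_days = pd.Series([s.day_index for s in stims])
    days = sorted(set(det_days.tolist()) | set(stim_days.tolist()))
    rows = []
    for day in days:
        n_bouts = int((stim_days == day).sum())
        stim_seconds = sum(s.duration_s for s in stims if s.day_index == day)
        rows.append(
            {
                "day_index": day,
                "detections": int((det_days == day).sum()),
                "bouts": n_bouts,
                "stimulated_min": stim_seconds / 60.0,
            }
        )
    return pd.DataFrame(rows, columns=["day_index", "detections", "bouts", "stimulated_min"])
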