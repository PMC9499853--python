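"""Wall-clock helpers for awake/sleep gating and daily accounting."""

from __future__ import annotations

from datetime import datetime, timedelta


def local_time(start_clock: datetime, t_s: float) -> datetime:
    """Local wall-clock time of a sample ``t_s`` seconds into the recording."""
    return start_clock + timedelta(seconds=float(t_s))


def in_hour_range(when: datetime, start_hour: float, end_hour: float) -> bool:
    """True if ``when`` falls in the local-hour interval [start, end).

    Handles intervals that wrap midnight (e.g. sleep 22:00-07:00).
    """
    h = when.hour + when.minute / 60 + when.second / 3600 + when.microsecond / 3.6e9
    if start_hour == end_hour:
        return False
    if start_hour < end_hour:
        return start_hour <= h < end_hour
    return h >= start_hour or h < end_hour


def day_index(start_clock: datetime, t_s: float) -> int:
    """Local calendar day of ``t_s``, counted from the recording's first day."""
    return (local_time(start_clock, t_s).date() - start_clock.date()).days


def hour_intervals(
    start_clock: datetime,
    duration_s: float,
    start_hour: float,
    end_hour: float,
) -> list[tuple[float, float]]:
    """Recording-time intervals (seconds) whose local hour lies in [start, end).

    Wrapping intervals are supported; returned intervals are clipped to
    ``[0, duration_s]``, non-empty, and sorted.
    """
    if start_hour == end_hour:
        return []
    day0 = datetime(start_clock.year, start_clock.month, start_clock.day)
    offset = (start_clock - day0).total_seconds()
    if start_hour < end_hour:
        windows = [(start_hour * 3600.0, end_hour * 3600.0)]
    else:  # wraps midnight: split into evening and morning pieces
        windows = [(start_hour * 3600.0, 86400.0), (0.0, end_hour * 3600.0)]
    out: list[tuple[float, float]] = []
    n_days = int(duration_s // 86400) + 2
    for day in range(n_days):
        for w0, w1 in windows:
            a = day * 86400.0 + w0 - offset
            b = day * 86400.0 + w1 - offset
            a, b = max(a, 0.0), min(b, float(duration_s))
            if b > a:
                out.append((a, b))
    out.sort()
    return out
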