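"""Behavioral event logs.

Events are the behavioral ground truth the electrophysiology is locked to:
video-annotated bites during in-lab meals, patient-initiated magnet swipes
tagging ambulatory craving / hunger / control moments, and device-scheduled
snapshot recordings during awake and sleep hours.  Each event carries optional
1-5 Likert self-report ratings (loss-of-control severity, craving, hunger).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

import pandas as pd

#: Recognized behavioral event kinds.
EVENT_KINDS = frozenset(
    {
        "bite_loc",
        "bite_standard",
        "magnet_craving",
        "magnet_hunger",
        "magnet_control",
        "scheduled_awake",
        "scheduled_sleep",
    }
)

#: Kinds confined to sleep hours; all others are awake-hour events.
SLEEP_KINDS = frozenset({"scheduled_sleep"})

_RATING_COLS = ("loc_rating", "craving_rating", "hunger_rating")


@dataclass(frozen=True)
class BehavioralEvent:
    """A single time-stamped behavioral event.

    Parameters
    ----------
    time_s
        Event time in seconds from the start of the recording.
    kind
        One of :data:`EVENT_KINDS`.
    loc_rating, craving_rating, hunger_rating
        Optional 1-5 Likert self-reports attached to the event.
    """

    time_s: float
    kind: str
    loc_rating: Optional[int] = None
    craving_rating: Optional[int] = None
    hunger_rating: Optional[int] = None

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        for name in _RATING_COLS:
            value = getattr(self, name)
            if value is not None and not 1 <= int(value) <= 5:
                raise ValueError(f"{name}={value!r} outside Likert range 1-5")


@dataclass
class EventLog:
    """Time-ordered collection of :class:`BehavioralEvent`."""

    events: list[BehavioralEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        times = [e.time_s for e in self.events]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValueError("event times must be non-decreasing")

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self) -> Iterator[BehavioralEvent]:
        return iter(self.events)

    def of_kind(self, kinds: str | Iterable[str]) -> list[BehavioralEvent]:
        if isinstance(kinds, str):
            kinds = {kinds}
        else:
            kinds = set(kinds)
        unknown = kinds - EVENT_KINDS
        if unknown:
            raise ValueError(f"unknown event kinds: {sorted(unknown)}")
        return [e for e in self.events if e.kind in kinds]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "time_s": e.time_s,
                "kind": e.kind,
                "loc_rating": e.loc_rating,
                "craving_rating": e.craving_rating,
                "hunger_rating": e.hunger_rating,
            }
            for e in self.events
        ]
        return pd.DataFrame(rows, columns=["time_s", "kind", *_RATING_COLS])

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "EventLog":
        events = []
        for row in frame.itertuples(index=False):
            ratings = {}
            for name in _RATING_COLS:
                value = getattr(row, name, None)
                if value is None or (isinstance(value, float) and math.isnan(value)):
                    ratings[name] = None
                else:
                    ratings[name] = int(value)
            events.append(BehavioralEvent(float(row.time_s), str(row.kind), **ratings))
        events.sort(key=lambda e: e.time_s)
        return cls(events)

    @classmethod
    def from_csv(cls, path: str | Path) -> "EventLog":
        return cls.from_frame(pd.read_csv(path))
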