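"""The LFP record container and its on-disk format.

A recording is a set of equal-length bipolar channels sampled at a common
rate, anchored to a wall-clock start time so that awake/sleep gating and the
daily stimulation budget can be evaluated in local time.  On disk a record is
a two-file container: raw little-endian 32-bit float samples stored
channel-major (``<prefix>.f32``) plus a YAML sidecar with the sampling rate,
channel roles, start clock and units (``<prefix>.yaml``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path

import numpy as np
import yaml

#: Canonical channel roles: one ventral and one dorsal bipolar pair per side.
CHANNEL_ROLES = ("left_ventral", "left_dorsal", "right_ventral", "right_dorsal")

#: The biomarker channels the detector runs on.
VENTRAL_ROLES = ("left_ventral", "right_ventral")


@dataclass
class LFPRecord:
    """Multichannel LFP voltage time series.

    Parameters
    ----------
    samples
        Array of shape ``(n_channels, n_samples)`` in microvolts.
    fs_hz
        Sampling rate in Hz.
    channel_roles
        Ordered role labels, one per row of ``samples``.
    start_clock
        Wall-clock time of sample 0 (local time).
    """

    samples: np.ndarray
    fs_hz: float
    channel_roles: tuple[str, ...]
    start_clock: datetime = field(default_factory=lambda: datetime(2021, 1, 1))
    units: str = "uV"

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=np.float64))
        self.channel_roles = tuple(self.channel_roles)
        if self.samples.shape[0] != len(self.channel_roles):
            raise ValueError(
                f"{self.samples.shape[0]} channels but "
                f"{len(self.channel_roles)} roles"
            )
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    def channel(self, role: str) -> np.ndarray:
        """Return the sample array for one channel role."""
        try:
            idx = self.channel_roles.index(role)
        except ValueError:
            raise KeyError(f"no channel with role {role!r}") from None
        return self.samples[idx]

    def write(self, prefix: str | Path) -> tuple[Path, Path]:
        """Write the ``.f32`` + ``.yaml`` container; returns both paths."""
        prefix = Path(prefix)
        raw_path = prefix.with_suffix(".f32")
        meta_path = prefix.with_suffix(".yaml")
        self.samples.astype("<f4").tofile(raw_path)
        meta = {
            "fs_hz": float(self.fs_hz),
            "channel_roles": list(self.channel_roles),
            "n_samples": int(self.n_samples),
            "start_clock": self.start_clock.isoformat(),
            "units": self.units,
            "dtype": "<f4",
            "layout": "channel_major",
        }
        meta_path.write_text(yaml.safe_dump(meta, sort_keys=False))
        return raw_path, meta_path

    @classmethod
    def read(cls, prefix: str | Path) -> "LFPRecord":
        prefix = Path(prefix)
        meta = yaml.safe_load(prefix.with_suffix(".yaml").read_text())
        raw = np.fromfile(prefix.with_suffix(".f32"), dtype="<f4")
        roles = tuple(meta["channel_roles"])
        samples = raw.reshape(len(roles), int(meta["n_samples"]))
        return cls(
            samples=samples.astype(np.float64),
            fs_hz=float(meta["fs_hz"]),
            channel_roles=roles,
            start_clock=datetime.fromisoformat(meta["start_clock"]),
            units=meta.get("units", "uV"),
        )
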