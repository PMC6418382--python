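"""Flat-binary + JSON-sidecar signal files and the CSV tables used across modules.

Continuous signals are stored as little-endian float32, C-order ``(n_samples,
n_channels)``, next to a ``.json`` sidecar holding ``fs``, ``n_channels``,
``channel_names``, ``units`` and ``t0``.  Event tables, spike tables and
trajectories are plain CSV with documented headers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ContinuousSignal",
    "EventSeries",
    "write_signal",
    "read_signal",
    "read_events_csv",
    "write_events_csv",
]


@dataclass
class ContinuousSignal:
    """A uniformly sampled single-channel signal (µV unless stated otherwise)."""

    samples: np.ndarray
    fs: float
    t0: float = 0.0
    name: str = "signal"
    units: str = "uV"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("ContinuousSignal holds a single channel")
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def t(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.fs

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs


@dataclass
class EventSeries:
    """Stimulation onset/offset times in seconds; the alignment backbone."""

    onsets: np.ndarray
    offsets: np.ndarray

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)
        self.offsets = np.asarray(self.offsets, dtype=float)
        if self.onsets.shape != self.offsets.shape:
            raise ValueError("onsets and offsets must have equal length")
        if np.any(self.offsets <= self.onsets):
            raise ValueError("each offset must follow its onset")
        if np.any(np.diff(self.onsets) <= 0):
            raise ValueError("onsets must be strictly increasing")

    def __len__(self) -> int:
        return self.onsets.size

    def anchors(self, anchor: str) -> np.ndarray:
        if anchor == "onset":
            return self.onsets
        if anchor == "offset":
            return self.offsets
        raise ValueError(f"unknown anchor {anchor!r}")

    @classmethod
    def from_csv(cls, path: str | Path) -> "EventSeries":
        df = pd.read_csv(path)
        return cls(df["onset_s"].to_numpy(), df["offset_s"].to_numpy())

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"onset_s": self.onsets, "offset_s": self.offsets}).to_csv(
            path, index=False
        )


def write_signal(
    prefix: str | Path,
    data: np.ndarray,
    fs: float,
    channel_names: list[str],
    units: str = "uV",
    t0: float = 0.0,
) -> None:
    """Write ``data`` of shape (n_samples, n_channels) as float32 .bin + .json sidecar."""
    prefix = Path(prefix)
    data = np.atleast_2d(np.asarray(data, dtype=np.float32))
    if data.shape[0] < data.shape[1] and data.shape[0] == len(channel_names):
        raise ValueError("data must be (n_samples, n_channels)")
    if data.shape[1] != len(channel_names):
        raise ValueError("channel_names length must match n_channels")
    data.astype("<f4").tofile(prefix.with_suffix(".bin"))
    sidecar = {
        "fs": fs,
        "n_channels": data.shape[1],
        "channel_names": list(channel_names),
        "units": units,
        "t0": t0,
    }
    prefix.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_signal(prefix: str | Path) -> tuple[np.ndarray, dict]:
    """Read a flat-binary signal; returns (data (n_samples, n_channels), sidecar dict)."""
    prefix = Path(prefix)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    raw = np.fromfile(prefix.with_suffix(".bin"), dtype="<f4")
    data = raw.reshape(-1, meta["n_channels"]).astype(float)
    return data, meta


def read_events_csv(path: str | Path) -> EventSeries:
    return EventSeries.from_csv(path)


def write_events_csv(events: EventSeries, path: str | Path) -> None:
    events.to_csv(path)
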