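"""Core containers for the accelerometer-to-behaviour pipeline.

The pipeline works on three kinds of time series, all anchored to wall-clock
timestamps so that clock-window operations (day vs night budgets) are direct:

* :class:`AccelTrace` -- a fixed-rate (default 40 Hz) tri-axial acceleration
  recording in units of g, device axes X = surge (front-back), Y = sway
  (side-side), Z = heave (up-down).  Missing spans are represented in place as
  NaN rows so that downstream windowed statistics become undefined exactly
  where data are absent.
* :class:`LabelSeries` -- one behaviour code per whole second.
* :class:`FocalRecord` -- one simulated focal follow: instantaneous scans at
  one-minute marks plus continuously-timed grooming bouts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The six mutually exclusive state behaviours, in the fixed (alphabetical)
#: class order used for classifier outputs and tie-breaking.
BEHAVIOURS: tuple[str, ...] = (
    "foraging",
    "giving_grooming",
    "receiving_grooming",
    "resting",
    "running",
    "walking",
)

#: Label for seconds whose behaviour is unknown (outside the six-state
#: vocabulary, or never observed).
UNLABELLED = "unlabelled"

#: Prediction code for epochs whose features are undefined.
UNCLASSIFIED = "unclassified"

#: Optional label for smeared transition seconds.
TRANSITION = "transition"

#: The 16 per-epoch acceleration variables, in canonical column order.
FEATURE_COLUMNS: tuple[str, ...] = (
    "stX", "stY", "stZ",
    "pitch", "roll",
    "VeDBA", "VeDBAs",
    "PDBAx", "PDBAy", "PDBAz",
    "PSD1X", "PSD2X", "PSD1Y", "PSD2Y", "PSD1Z", "PSD2Z",
)


@dataclass
class AccelTrace:
    """A contiguous fixed-rate tri-axial acceleration recording in g."""

    individual_id: str
    start_time: pd.Timestamp
    rate_hz: int
    samples: np.ndarray  # shape (n, 3), float; NaN rows mark missing spans

    def __post_init__(self) -> None:
        self.start_time = pd.Timestamp(self.start_time)
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ValueError("samples must have shape (n, 3)")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        if np.isinf(self.samples).any():
            raise ValueError("acceleration samples must be finite or NaN")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate_hz

    def times(self) -> pd.DatetimeIndex:
        offsets = pd.to_timedelta(np.arange(self.n_samples) / self.rate_hz, unit="s")
        return pd.DatetimeIndex(self.start_time + offsets)

    def missing_spans(self) -> list[tuple[int, int]]:
        """Half-open sample-index ranges where any axis is NaN."""
        bad = np.isnan(self.samples).any(axis=1)
        return _runs(bad)


@dataclass
class LabelSeries:
    """Per-second behaviour codes, contiguous from ``start_time``."""

    individual_id: str
    start_time: pd.Timestamp
    labels: np.ndarray  # shape (n,), str

    def __post_init__(self) -> None:
        self.start_time = pd.Timestamp(self.start_time).floor("s")
        self.labels = np.asarray(self.labels, dtype=object)

    @property
    def duration_s(self) -> int:
        return len(self.labels)

    def times(self) -> pd.DatetimeIndex:
        return self.start_time + pd.to_timedelta(np.arange(len(self.labels)), unit="s")

    def state_seconds(self) -> int:
        """Number of seconds carrying one of the six state behaviours."""
        return int(np.isin(self.labels.astype(str), BEHAVIOURS).sum())


@dataclass
class FocalRecord:
    """One focal follow: minute scans plus continuously-timed grooming bouts.

    ``scans`` holds (minute_index, behaviour) pairs; a non-extended 30-minute
    follow has 31 scans (minutes 0..30 inclusive).  ``grooming_bouts`` holds
    (role, start_s, end_s) with role "give" or "receive" and times in seconds
    relative to ``start_time``; bouts running past the nominal end extend
    ``duration_s``.
    """

    individual_id: str
    start_time: pd.Timestamp
    scans: list[tuple[int, str]]
    grooming_bouts: list[tuple[str, float, float]]
    duration_s: float
    follow_id: int = field(default=0)

    def __post_init__(self) -> None:
        self.start_time = pd.Timestamp(self.start_time)
        if self.duration_s < 180:
            raise ValueError("a usable focal follow must last at least 3 min")
        for role, s, e in self.grooming_bouts:
            if role not in ("give", "receive"):
                raise ValueError(f"unknown grooming role: {role!r}")
            if not (0 <= s < e <= self.duration_s):
                raise ValueError("grooming bout outside the follow window")


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open index ranges of consecutive True values."""
    if mask.size == 0:
        return []
    edges = np.flatnonzero(np.diff(mask.astype(np.int8)))
    starts = list(edges[mask[edges + 1]] + 1)
    ends = list(edges[~mask[edges + 1]] + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(mask.size)
    return list(zip(starts, ends))


def label_runs(labels: np.ndarray) -> list[tuple[int, int, str]]:
    """Run-length encode a label array into (start, stop, label) with
    half-open [start, stop) index ranges."""
    out: list[tuple[int, int, str]] = []
    n = len(labels)
    i = 0
    while i < n:
        j = i + 1
        while j < n and labels[j] == labels[i]:
            j += 1
        out.append((i, j, str(labels[i])))
        i = j
    return out
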