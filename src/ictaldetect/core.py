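"""Shared domain types and interval arithmetic.

All interval coordinates in this package are half-open ``[start, end)`` in
0-based sample (or frame) indices; seconds are obtained through the sampling
rate ``fs`` (or ``fps`` for video).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ParameterError",
    "DataError",
    "ChannelSeries",
    "EventLabelSet",
    "AnomalyInterval",
    "merge_intervals",
    "intervals_to_array",
]


class ParameterError(ValueError):
    """A configuration or argument value violates an operation's contract."""


class DataError(ValueError):
    """Input data violates an invariant (non-finite values, bad labels, ...)."""


@dataclass
class ChannelSeries:
    """One uniformly sampled channel of a recording.

    Parameters
    ----------
    values:
        1-D float array. Arbitrary units (microvolts for raw SEEG,
        dimensionless after scaling, [0, 1] for video regularity scores).
    fs:
        Sampling rate in Hz. Must be positive.
    patient_id, channel_id:
        Provenance identifiers; carried through preprocessing and training so
        crossover runs (a model from one patient applied to another) can be
        detected and logged.
    start_index:
        Sample offset of ``values[0]`` relative to the start of the original
        recording. Train/test splitting sets this so detections on the test
        segment can be mapped back to absolute recording coordinates.
    """

    values: np.ndarray
    fs: float
    patient_id: str = ""
    channel_id: str = ""
    start_index: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise DataError("ChannelSeries values must be 1-D")
        if self.values.size < 1:
            raise DataError("ChannelSeries must contain at least one sample")
        if not np.all(np.isfinite(self.values)):
            raise DataError("ChannelSeries values must be finite")
        if not (self.fs > 0):
            raise ParameterError(f"sampling rate must be positive, got {self.fs}")

    def __len__(self) -> int:
        return int(self.values.size)

    @property
    def duration_s(self) -> float:
        return len(self) / self.fs

    def with_values(self, values: np.ndarray, **changes) -> "ChannelSeries":
        """Copy of this series with new samples (and optional field changes)."""
        return replace(self, values=np.asarray(values, dtype=float), **changes)


def _normalize_intervals(intervals, strict: bool) -> np.ndarray:
    arr = intervals_to_array(intervals)
    if arr.shape[0] == 0:
        return arr
    if np.any(arr[:, 0] >= arr[:, 1]):
        bad = arr[arr[:, 0] >= arr[:, 1]][0]
        raise DataError(f"inverted or empty interval ({bad[0]}, {bad[1]})")
    order = np.argsort(arr[:, 0], kind="stable")
    arr = arr[order]
    overlapping = np.any(arr[1:, 0] < arr[:-1, 1])
    if overlapping:
        if strict:
            raise DataError("overlapping intervals in strict mode")
        warnings.warn("overlapping intervals merged", stacklevel=3)
        arr = merge_intervals(arr, gap=0)
    return arr


@dataclass
class EventLabelSet:
    """Ground-truth event intervals for one recording.

    ``intervals`` is an ``(k, 2)`` integer array of half-open
    ``[start_sample, end_sample)`` pairs, sorted and non-overlapping after
    normalization. ``source`` records where the labels came from
    (``"consensus"`` for expert panel labels, ``"synthetic-truth"`` for
    generator output).
    """

    intervals: np.ndarray
    fs: float
    source: str = "consensus"
    strict: bool = False

    def __post_init__(self) -> None:
        if not (self.fs > 0):
            raise ParameterError("fs must be positive")
        self.intervals = _normalize_intervals(self.intervals, strict=self.strict)

    def __len__(self) -> int:
        return int(self.intervals.shape[0])

    def shifted(self, offset: int) -> "EventLabelSet":
        """Labels translated by ``offset`` samples (e.g. into test-segment coords)."""
        return EventLabelSet(self.intervals + int(offset), fs=self.fs, source=self.source)

    def clipped(self, start: int, end: int) -> "EventLabelSet":
        """Labels intersected with ``[start, end)``; empty results dropped."""
        arr = self.intervals.copy()
        if arr.shape[0]:
            arr[:, 0] = np.maximum(arr[:, 0], start)
            arr[:, 1] = np.minimum(arr[:, 1], end)
            arr = arr[arr[:, 0] < arr[:, 1]]
        return EventLabelSet(arr, fs=self.fs, source=self.source)


@dataclass
class AnomalyInterval:
    """One detected anomalous run of the smoothed error series.

    ``start``/``end`` are half-open indices on the series the detector ran on
    (samples for SEEG, frames for video); ``peak_error`` is the maximum
    smoothed error inside the run, which is what the pruning step ranks.
    """

    start: int
    end: int
    peak_error: float = 0.0
    modality: str = "seeg"
    channel_id: str = ""
    provenance: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.start = int(self.start)
        self.end = int(self.end)
        if self.start >= self.end:
            raise DataError(f"inverted interval ({self.start}, {self.end})")
        if self.peak_error < 0:
            raise DataError("peak_error must be nonnegative")
        if not self.provenance:
            self.provenance = frozenset({self.modality})

    def overlaps(self, start: int, end: int) -> bool:
        return self.start < end and start < self.end

    def shifted(self, offset: int) -> "AnomalyInterval":
        return replace(self, start=self.start + offset, end=self.end + offset)

    def rescaled(self, factor: float) -> "AnomalyInterval":
        """Map to another time base (e.g. video frames -> SEEG samples)."""
        start = int(np.floor(self.start * factor))
        end = int(np.ceil(self.end * factor))
        return replace(self, start=start, end=max(end, start + 1))


def intervals_to_array(intervals) -> np.ndarray:
    """Coerce a list of pairs / AnomalyIntervals / (k,2) array to int array."""
    if isinstance(intervals, np.ndarray):
        arr = intervals
    else:
        pairs = [
            (iv.start, iv.end) if isinstance(iv, AnomalyInterval) else tuple(iv)
            for iv in intervals
        ]
        arr = np.asarray(pairs, dtype=np.int64)
    arr = np.asarray(arr, dtype=np.int64).reshape(-1, 2)
    return arr


def merge_intervals(intervals, gap: int = 0) -> np.ndarray:
    """Union of half-open intervals, merging pairs separated by <= ``gap``.

    Returns a sorted, non-overlapping ``(k, 2)`` int array.
    """
    arr = intervals_to_array(intervals)
    if arr.shape[0] == 0:
        return arr
    arr = arr[np.argsort(arr[:, 0], kind="stable")]
    out = [list(arr[0])]
    for s, e in arr[1:]:
        if s <= out[-1][1] + gap:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return np.asarray(out, dtype=np.int64)
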