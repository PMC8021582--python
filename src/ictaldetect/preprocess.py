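"""Filtering, scaling, and chronological train/test splitting.

The SEEG path applies a one-pass, zero-phase, non-causal 50 Hz low-pass FIR
filter and scales amplitudes to [-1, 1] before any model sees the data.
The filter is a windowed-sinc (Hamming) design applied once with group-delay
compensation; reflection padding keeps the output the same length as the
input. Scaling parameters are fit on the training segment only and reused on
the test segment so no information leaks across the split.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .core import ChannelSeries, ParameterError

__all__ = [
    "design_lowpass",
    "lowpass_filter",
    "MinMaxParams",
    "scale_minmax",
    "apply_minmax",
    "SplitSpec",
    "split_train_test",
]


def design_lowpass(fs: float, cutoff_hz: float = 50.0,
                   transition_hz: float = 12.5) -> np.ndarray:
    """Hamming windowed-sinc low-pass FIR taps (odd length, linear phase).

    The order follows the Hamming window's ~3.3/N normalized transition
    width, so the stop band begins about ``transition_hz`` above the cutoff.
    """
    if not (0 < cutoff_hz < fs / 2):
        raise ParameterError(
            f"cutoff {cutoff_hz} Hz must lie below the Nyquist rate {fs / 2} Hz"
        )
    numtaps = int(np.ceil(3.3 * fs / transition_hz))
    if numtaps % 2 == 0:
        numtaps += 1
    return sps.firwin(numtaps, cutoff_hz, window="hamming", fs=fs)


def lowpass_filter(series: ChannelSeries, cutoff_hz: float = 50.0,
                   transition_hz: float = 12.5) -> ChannelSeries:
    """One-pass, zero-phase low-pass filter (symmetric FIR, delay-compensated).

    The symmetric taps are applied once; centering the convolution compensates
    the (numtaps-1)/2 group delay exactly, so there is no phase distortion.
    Edges are handled by reflection padding.
    """
    taps = design_lowpass(series.fs, cutoff_hz, transition_hz)
    n = len(series)
    pad = taps.size  # >= half the filter length; generous reflect padding
    if n <= taps.size:
        raise ParameterError(
            f"series of {n} samples is shorter than the {taps.size}-tap filter"
        )
    padded = np.pad(series.values, pad, mode="reflect")
    # 'same' centers the symmetric kernel -> zero phase in one pass
    filtered = sps.fftconvolve(padded, taps, mode="same")[pad:-pad]
    return series.with_values(filtered)


@dataclass(frozen=True)
class MinMaxParams:
    """Affine scaling parameters fit on one segment, reusable on another."""

    vmin: float
    vmax: float

    @property
    def degenerate(self) -> bool:
        return self.vmax == self.vmin

    def transform(self, values: np.ndarray) -> np.ndarray:
        if self.degenerate:
            return np.zeros_like(np.asarray(values, dtype=float))
        return 2.0 * (np.asarray(values, dtype=float) - self.vmin) / (self.vmax - self.vmin) - 1.0


def scale_minmax(series: ChannelSeries) -> tuple[ChannelSeries, MinMaxParams]:
    """Scale so the segment's min maps to -1 and its max to +1.

    A constant segment maps to all zeros (the midpoint), the documented
    degenerate convention. Returns the scaled series and the fitted
    parameters for reuse on held-out data.
    """
    params = MinMaxParams(vmin=float(np.min(series.values)),
                          vmax=float(np.max(series.values)))
    return series.with_values(params.transform(series.values)), params


def apply_minmax(series: ChannelSeries, params: MinMaxParams) -> ChannelSeries:
    """Apply previously fitted scaling; values outside the fitted range may
    exceed [-1, 1] (not clipped, so genuine out-of-range activity stays visible)."""
    return series.with_values(params.transform(series.values))


@dataclass(frozen=True)
class SplitSpec:
    """Chronological, contiguous train/test split.

    ``train_fraction`` defaults to 0.30, inside the 20:80-50:50 band the
    training regimen uses; the training segment always precedes the test
    segment.
    """

    train_fraction: float = 0.30

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise ParameterError("train_fraction must lie in (0, 1)")

    def split_point(self, n: int) -> int:
        return int(round(n * self.train_fraction))


def split_train_test(series: ChannelSeries, spec: SplitSpec = SplitSpec(),
                     min_train: int = 2) -> tuple[ChannelSeries, ChannelSeries]:
    """Split into (train, test); concatenating them reconstructs the input.

    ``min_train`` guards against training segments too short for the
    forecaster's history window.
    """
    n = len(series)
    point = spec.split_point(n)
    if point < min_train:
        raise ParameterError(
            f"train segment of {point} samples is shorter than the required {min_train}"
        )
    if point >= n:
        raise ParameterError("test segment would be empty")
    train = series.with_values(series.values[:point])
    test = series.with_values(series.values[point:],
                              start_index=series.start_index + point)
    return train, test
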