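"""Nonparametric dynamic thresholding of smoothed errors, with pruning.

The detector slides a window over the smoothed error series ``e_s`` and, in
each window, picks the threshold ``eps = mu + z * sigma`` (``z`` from a small
grid) that maximizes the percent decrease in the window's mean and standard
deviation when the values above ``eps`` are excluded:

    objective(z) = (dmu / mu + dsigma / sigma) / penalty
    penalty      = n_above + n_runs**2      (penalized form, the default)

where ``dmu``/``dsigma`` are the drops in mean/sd after exclusion, ``n_above``
counts points strictly above ``eps`` and ``n_runs`` counts contiguous runs of
them. No distributional assumption is made about the errors — the method is
chosen precisely because forecast residuals are usually non-Gaussian.
Detected runs are then pruned: ranked by peak error, a run survives only if
it sits above the last inter-peak percent-drop greater than ``p`` (default
10%); otherwise it is reclassified as normal. A conventional global
``mean + k*sd`` static threshold is provided as the baseline.

Population (ddof=0) standard deviations and strict exceedance (``e_s > eps``)
are used throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .core import AnomalyInterval, ParameterError, merge_intervals

__all__ = [
    "ThresholdDecision",
    "DynamicConfig",
    "threshold_objective",
    "find_dynamic_threshold",
    "detect_anomalous_sequences",
    "prune_anomalies",
    "static_threshold_detect",
]

_DEFAULT_Z_GRID = tuple(np.arange(2.0, 10.0 + 1e-9, 0.5))


@dataclass(frozen=True)
class ThresholdDecision:
    """A chosen window threshold and the diagnostics behind it."""

    epsilon: float
    z: float
    mu: float
    sigma: float
    delta_mu: float
    delta_sigma: float
    n_anom_points: int
    n_anom_seqs: int
    objective_value: float
    no_anomaly: bool = False

    def to_json(self) -> str:
        return json.dumps(self.__dict__, default=float)


@dataclass(frozen=True)
class DynamicConfig:
    """Sliding-window dynamic thresholding configuration.

    ``window_size``/``step`` are in samples of the smoothed error series; the
    z grid spans 2..10 in steps of 0.5; the penalized objective (divide by
    ``n_above + n_runs**2``) is the default; ``prune_p`` is the percent-drop
    pruning level (0.10 = 10%).
    """

    window_size: int = 2048
    step: int | None = None
    z_grid: tuple = _DEFAULT_Z_GRID
    penalized: bool = True
    prune_p: float = 0.10
    prune_scope: str = "both"
    merge_gap: int = 0

    def __post_init__(self) -> None:
        if self.window_size < 10:
            raise ParameterError("window_size must be >= 10")
        if self.step is not None and self.step < 1:
            raise ParameterError("step must be >= 1")
        if len(self.z_grid) == 0:
            raise ParameterError("z_grid must be nonempty")
        if any(z < 0 for z in self.z_grid):
            raise ParameterError("z_grid values must be nonnegative")
        if not (0.0 <= self.prune_p <= 1.0):
            raise ParameterError("prune_p must lie in [0, 1]")
        if self.prune_scope not in ("window", "global", "both", "none"):
            raise ParameterError(
                "prune_scope must be 'window', 'global', 'both', or 'none'")

    @property
    def effective_step(self) -> int:
        return self.step if self.step is not None else max(1, self.window_size // 2)


def _count_runs(mask: np.ndarray) -> int:
    if not mask.any():
        return 0
    diffs = np.diff(mask.astype(np.int8))
    return int(mask[0]) + int(np.sum(diffs == 1))


def _runs_from_mask(mask: np.ndarray) -> np.ndarray:
    """Half-open [start, end) runs of True in a boolean mask."""
    padded = np.concatenate(([False], mask, [False])).astype(np.int8)
    diffs = np.diff(padded)
    starts = np.flatnonzero(diffs == 1)
    ends = np.flatnonzero(diffs == -1)
    return np.stack([starts, ends], axis=1).astype(np.int64)


def threshold_objective(e_s_window, z: float, penalized: bool = True
                        ) -> tuple[float, float, ThresholdDecision]:
    """Evaluate the exclusion objective for one window at one ``z``.

    Returns ``(epsilon, objective_value, decision)``. The objective is 0 when
    no point strictly exceeds ``epsilon`` (nothing to exclude) and in the
    degenerate all-equal window (sigma = 0).
    """
    w = np.asarray(e_s_window, dtype=float)
    if w.size < 2:
        raise ParameterError("window must contain at least 2 values")
    mu = float(np.mean(w))
    sigma = float(np.std(w))  # population sd
    if sigma == 0.0:
        decision = ThresholdDecision(epsilon=mu, z=float(z), mu=mu, sigma=0.0,
                                     delta_mu=0.0, delta_sigma=0.0,
                                     n_anom_points=0, n_anom_seqs=0,
                                     objective_value=0.0, no_anomaly=True)
        return mu, 0.0, decision
    eps = mu + z * sigma
    above = w > eps
    below = w < eps
    n_above = int(np.count_nonzero(above))
    if n_above == 0 or not below.any():
        decision = ThresholdDecision(epsilon=eps, z=float(z), mu=mu, sigma=sigma,
                                     delta_mu=0.0, delta_sigma=0.0,
                                     n_anom_points=n_above,
                                     n_anom_seqs=_count_runs(above),
                                     objective_value=0.0,
                                     no_anomaly=(n_above == 0))
        return eps, 0.0, decision
    remaining = w[below]
    delta_mu = mu - float(np.mean(remaining))
    delta_sigma = sigma - float(np.std(remaining))
    objective = delta_mu / mu + delta_sigma / sigma
    n_runs = _count_runs(above)
    if penalized:
        objective /= (n_above + n_runs ** 2)
    decision = ThresholdDecision(epsilon=eps, z=float(z), mu=mu, sigma=sigma,
                                 delta_mu=delta_mu, delta_sigma=delta_sigma,
                                 n_anom_points=n_above, n_anom_seqs=n_runs,
                                 objective_value=float(objective))
    return eps, float(objective), decision


def find_dynamic_threshold(e_s_window, config: DynamicConfig = DynamicConfig()
                           ) -> ThresholdDecision:
    """Pick the ``z`` in the grid maximizing the objective (ties -> larger z).

    Equivalent to exhaustively evaluating :func:`threshold_objective` at every
    grid point; an all-equal window yields a no-anomaly decision.
    """
    w = np.asarray(e_s_window, dtype=float)
    if w.size < 2:
        raise ParameterError("window must contain at least 2 values")
    best: ThresholdDecision | None = None
    for z in config.z_grid:  # ascending grid; >= keeps the larger z on ties
        _, objective, decision = threshold_objective(w, z, config.penalized)
        if best is None or objective >= best.objective_value:
            best = decision
    assert best is not None
    return best


def window_exceedance_mask(window: np.ndarray, config: DynamicConfig) -> np.ndarray:
    """Boolean anomaly mask for one window: local threshold, then (by default)
    pruning of the window's runs against its own error landscape."""
    decision = find_dynamic_threshold(window, config)
    if decision.no_anomaly or decision.n_anom_points == 0:
        return np.zeros(window.size, dtype=bool)
    mask = window > decision.epsilon
    if config.prune_scope in ("window", "both"):
        local = [
            AnomalyInterval(start=a, end=b, peak_error=float(np.max(window[a:b])))
            for a, b in _runs_from_mask(mask)
        ]
        kept = prune_anomalies(local, window, p=config.prune_p)
        mask = np.zeros_like(mask)
        for iv in kept:
            mask[iv.start:iv.end] = True
    return mask


def detect_anomalous_sequences(e_s, config: DynamicConfig = DynamicConfig(),
                               modality: str = "seeg", channel_id: str = ""
                               ) -> list[AnomalyInterval]:
    """Slide windows over ``e_s``, flag exceedances of each local threshold,
    union the flags across windows, and merge into intervals.

    With ``prune_scope='window'`` (the default, matching the incremental
    stepping of the source method) each window's exceedance runs are pruned
    against that window's own error landscape before the union, so a window
    of undifferentiated noise humps contributes nothing while a window
    containing a true event keeps it. ``prune_scope='global'`` defers pruning
    to a single :func:`prune_anomalies` pass over the merged intervals (the
    caller applies it); ``'none'`` disables pruning.

    The final window is anchored to the end of the series so every sample is
    covered. Returned intervals are sorted, non-overlapping, and annotated
    with the peak smoothed error inside each run.
    """
    values = np.asarray(getattr(e_s, "e_s", e_s), dtype=float)
    n = values.size
    if n < config.window_size:
        raise ParameterError(
            f"series of {n} points is shorter than window_size {config.window_size}"
        )
    step = config.effective_step
    starts = list(range(0, n - config.window_size + 1, step))
    if starts[-1] != n - config.window_size:
        starts.append(n - config.window_size)
    flagged = np.zeros(n, dtype=bool)
    for s in starts:
        window = values[s:s + config.window_size]
        flagged[s:s + config.window_size] |= window_exceedance_mask(window, config)
    runs = merge_intervals(_runs_from_mask(flagged), gap=config.merge_gap)
    return [
        AnomalyInterval(start=s, end=e, peak_error=float(np.max(values[s:e])),
                        modality=modality, channel_id=channel_id)
        for s, e in runs
    ]


def prune_anomalies(intervals: list[AnomalyInterval], e_s, p: float = 0.10,
                    exclusion_pad: int = 0) -> list[AnomalyInterval]:
    """Reclassify weakly separated detections as normal.

    Peak errors are sorted descending (m_1 >= ... >= m_k) and followed by the
    largest smoothed error outside all intervals (m_{k+1}, 0 if none). With
    percent drops d_i = (m_i - m_{i+1}) / m_i, the intervals whose peaks rank
    at or above the *last* drop greater than ``p`` survive; if no drop
    exceeds ``p`` every interval is reclassified as normal.

    ``exclusion_pad`` widens each interval by that many samples when locating
    the outside maximum: on EWMA-smoothed errors the samples just beyond a
    flagged run are the filter's own relaxation tail, not nominal background,
    so callers pass the smoothing span here.
    """
    if not intervals:
        return []
    values = np.asarray(getattr(e_s, "e_s", e_s), dtype=float)
    outside = np.ones(values.size, dtype=bool)
    for iv in intervals:
        outside[max(0, iv.start - exclusion_pad): iv.end + exclusion_pad] = False
    nominal_max = float(np.max(values[outside])) if outside.any() else 0.0

    ordered = sorted(intervals, key=lambda iv: iv.peak_error, reverse=True)
    peaks = np.array([iv.peak_error for iv in ordered] + [nominal_max])
    with np.errstate(divide="ignore", invalid="ignore"):
        drops = np.where(peaks[:-1] > 0,
                         (peaks[:-1] - peaks[1:]) / peaks[:-1], 0.0)
    exceed = np.flatnonzero(drops > p)
    if exceed.size == 0:
        return []
    cutoff = peaks[exceed[-1]]  # smallest surviving peak value
    kept = [iv for iv in ordered if iv.peak_error >= cutoff]
    return sorted(kept, key=lambda iv: iv.start)


def static_threshold_detect(e_s, k: float = 2.0, modality: str = "seeg",
                            channel_id: str = "", merge_gap: int = 0
                            ) -> list[AnomalyInterval]:
    """Baseline: one global ``mean + k*sd`` threshold over the whole series."""
    values = np.asarray(getattr(e_s, "e_s", e_s), dtype=float)
    if values.size < 2:
        raise ParameterError("series must contain at least 2 values")
    mu = float(np.mean(values))
    sigma = float(np.std(values))
    if sigma == 0.0:
        return []
    eps = mu + k * sigma
    runs = merge_intervals(_runs_from_mask(values > eps), gap=merge_gap)
    return [
        AnomalyInterval(start=s, end=e, peak_error=float(np.max(values[s:e])),
                        modality=modality, channel_id=channel_id)
        for s, e in runs
    ]
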