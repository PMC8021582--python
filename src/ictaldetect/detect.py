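"""End-to-end single-channel detection: split -> forecast -> smooth -> threshold.

This is the path both modalities share. A channel (SEEG sample series or
video regularity-score series) is split chronologically, a forecaster is
trained on the head segment (or a pre-trained, possibly foreign, model is
supplied — the crossover case), rolling one-step predictions on the tail
segment are turned into a smoothed error series, and the dynamic (or static
baseline) threshold converts that into anomaly intervals, mapped back to the
input series' absolute coordinates.

A streaming variant processes the test segment in chronological chunks and
produces bit-identical output to the batch path (no step looks past the
current window), honoring the real-time framing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .core import AnomalyInterval, ChannelSeries, ParameterError, merge_intervals
from .forecast import (
    ForecastConfig,
    SmoothedErrorSeries,
    UndefinedMetricError,
    default_span,
    fit_ar_baseline,
    forecast,
    mape,
    smoothed_error,
    train_forecaster,
)
from .preprocess import SplitSpec, split_train_test
from .threshold import (
    DynamicConfig,
    detect_anomalous_sequences,
    prune_anomalies,
    static_threshold_detect,
    window_exceedance_mask,
)

__all__ = ["DetectionResult", "detect_on_series", "detect_streaming"]


@dataclass
class DetectionResult:
    """Everything one detection run produced.

    ``intervals`` are the final (pruned, for the dynamic method) detections in
    absolute coordinates of the input series; ``raw_intervals`` are the
    pre-pruning detections; ``offset`` is the absolute index of
    ``errors.e_s[0]``.
    """

    intervals: list[AnomalyInterval]
    raw_intervals: list[AnomalyInterval]
    errors: SmoothedErrorSeries
    predictions: np.ndarray
    mape: float | None
    offset: int
    model: object
    method: str = "dynamic"


def _make_model(train: ChannelSeries, forecaster, forecast_config: ForecastConfig,
                ar_order: int):
    if forecaster == "ar":
        return fit_ar_baseline(train, order=ar_order,
                               history_window=forecast_config.history_window,
                               horizon=forecast_config.horizon)
    if forecaster == "lstm":
        return train_forecaster(train, forecast_config)
    raise ParameterError(f"unknown forecaster kind {forecaster!r}")


def detect_on_series(series: ChannelSeries,
                     model=None,
                     forecaster: str = "ar",
                     forecast_config: ForecastConfig = ForecastConfig(),
                     ar_order: int = 16,
                     split: SplitSpec = SplitSpec(),
                     dynamic: DynamicConfig = DynamicConfig(),
                     method: str = "dynamic",
                     static_k: float = 2.0,
                     span: int | None = None,
                     modality: str = "seeg") -> DetectionResult:
    """Run the full self-supervised detection path on one channel.

    ``series`` should already be preprocessed (filtered/scaled for SEEG; a
    regularity score is used as-is). If ``model`` is given the training step
    is skipped — this is how crossover runs apply a foreign patient's model.
    ``method`` selects the dynamic threshold (with pruning) or the global
    ``mean + k*sd`` static baseline on the identical error series.
    """
    l_b = forecast_config.history_window
    train, test = split_train_test(series, split,
                                   min_train=l_b + forecast_config.horizon + 1)
    if model is None:
        model = _make_model(train, forecaster, forecast_config, ar_order)
    preds = forecast(model, test)
    actual = test.values[model.history_window:]
    errors = smoothed_error(actual, preds, span=span, fs=series.fs,
                            source_channel=series.channel_id)
    offset = test.start_index + model.history_window
    if method == "dynamic":
        raw = detect_anomalous_sequences(errors.e_s, dynamic, modality=modality,
                                         channel_id=series.channel_id)
        if dynamic.prune_scope in ("global", "both"):
            # the pad keeps each run's own EWMA relaxation tail out of the
            # "nominal background" maximum
            pruned = prune_anomalies(raw, errors.e_s, p=dynamic.prune_p,
                                     exclusion_pad=errors.smoothing_span)
        else:
            pruned = raw
    elif method == "static":
        raw = static_threshold_detect(errors.e_s, k=static_k, modality=modality,
                                      channel_id=series.channel_id)
        pruned = raw
    else:
        raise ParameterError(f"unknown method {method!r}")
    try:
        mape_value = mape(actual, preds)
    except UndefinedMetricError:
        mape_value = None
    return DetectionResult(
        intervals=[iv.shifted(offset) for iv in pruned],
        raw_intervals=[iv.shifted(offset) for iv in raw],
        errors=errors,
        predictions=preds,
        mape=mape_value,
        offset=offset,
        model=model,
        method=method,
    )


def detect_streaming(series: ChannelSeries,
                     chunk: int = 4096,
                     model=None,
                     forecaster: str = "ar",
                     forecast_config: ForecastConfig = ForecastConfig(),
                     ar_order: int = 16,
                     split: SplitSpec = SplitSpec(),
                     dynamic: DynamicConfig = DynamicConfig(),
                     span: int | None = None,
                     modality: str = "seeg") -> DetectionResult:
    """Chronological chunked variant of :func:`detect_on_series` (dynamic method).

    The test segment arrives in chunks; forecasts, the EWMA recursion (carried
    across chunks via its one-value state) and each threshold window are
    computed as soon as their inputs are complete. Because no step uses data
    beyond its own window, the output is identical to the batch path.
    """
    l_b = forecast_config.history_window
    train, test = split_train_test(series, split,
                                   min_train=l_b + forecast_config.horizon + 1)
    if model is None:
        model = _make_model(train, forecaster, forecast_config, ar_order)
    n_targets = len(test) - model.history_window
    if span is None:
        span = default_span(n_targets)
    alpha = 2.0 / (span + 1)

    raw_all = np.empty(n_targets)
    preds_all = np.empty(n_targets)
    es_all = np.empty(n_targets)
    zi = None
    produced = 0
    flagged = np.zeros(n_targets, dtype=bool)
    next_start = 0  # next regular threshold-window start (multiples of step)
    W, step = dynamic.window_size, dynamic.effective_step

    for lo in range(0, len(test), chunk):
        hi = min(lo + chunk, len(test))
        # targets whose full history is available once sample hi-1 has arrived
        t_hi = hi - model.history_window
        if t_hi <= produced:
            continue
        seg = test.values[produced: t_hi + model.history_window]
        preds = forecast(model, ChannelSeries(seg, fs=test.fs,
                                              patient_id=test.patient_id,
                                              channel_id=test.channel_id))
        raw = np.abs(test.values[produced + model.history_window: hi] - preds)
        if zi is None:
            # EWMA recursion seeded with the first raw error (adjust=False)
            es, zf = sps.lfilter([alpha], [1.0, -(1.0 - alpha)], raw[1:],
                                 zi=[(1.0 - alpha) * raw[0]])
            es = np.concatenate([[raw[0]], es])
        else:
            es, zf = sps.lfilter([alpha], [1.0, -(1.0 - alpha)], raw, zi=zi)
        zi = zf
        raw_all[produced: t_hi] = raw
        preds_all[produced: t_hi] = preds
        es_all[produced: t_hi] = es
        produced = t_hi
        # threshold every regular window that is now complete
        while next_start + W <= produced:
            window = es_all[next_start: next_start + W]
            flagged[next_start: next_start + W] |= window_exceedance_mask(window, dynamic)
            next_start += step
    if produced < W:
        raise ParameterError("error series shorter than window_size")
    # the batch path anchors a final window to the series end
    tail_start = produced - W
    if tail_start % step != 0:
        flagged[tail_start:] |= window_exceedance_mask(es_all[tail_start:], dynamic)

    padded = np.concatenate(([False], flagged, [False])).astype(np.int8)
    diffs = np.diff(padded)
    runs = np.stack([np.flatnonzero(diffs == 1), np.flatnonzero(diffs == -1)], axis=1)
    runs = merge_intervals(runs, gap=dynamic.merge_gap)
    raw_intervals = [
        AnomalyInterval(start=s, end=e, peak_error=float(np.max(es_all[s:e])),
                        modality=modality, channel_id=series.channel_id)
        for s, e in runs
    ]
    if dynamic.prune_scope in ("global", "both"):
        pruned = prune_anomalies(raw_intervals, es_all, p=dynamic.prune_p,
                                 exclusion_pad=span)
    else:
        pruned = raw_intervals
    offset = test.start_index + model.history_window
    errors = SmoothedErrorSeries(e_s=es_all, raw=raw_all, smoothing_span=span,
                                 fs=series.fs, source_channel=series.channel_id)
    try:
        mape_value = mape(test.values[model.history_window:], preds_all)
    except UndefinedMetricError:
        mape_value = None
    return DetectionResult(
        intervals=[iv.shifted(offset) for iv in pruned],
        raw_intervals=[iv.shifted(offset) for iv in raw_intervals],
        errors=errors,
        predictions=preds_all,
        mape=mape_value,
        offset=offset,
        model=model,
        method="dynamic",
    )
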