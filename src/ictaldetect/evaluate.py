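"""Pooling detections across channels/modalities and event-level scoring.

Detections from all channels of a patient (and, for multimodal runs, from the
video path mapped onto the SEEG time base) are pooled by union-merge, then
compared with ground-truth event labels. A predicted interval counts as a
true positive if it overlaps at least one truth event (any-overlap rule, the
default; an IoU rule is available); a truth event counts as detected if at
least one prediction overlaps it. PPV and sensitivity are reported as
percentages, F1 as the harmonic mean of the proportions. Zero-denominator
metrics (e.g. PPV with no predictions at all) are reported as undefined, not
as 0 — mirroring "no events detected" rather than pretending a precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import AnomalyInterval, EventLabelSet, ParameterError, intervals_to_array
from .detect import detect_on_series
from .forecast import ForecastConfig
from .preprocess import SplitSpec
from .threshold import DynamicConfig

__all__ = [
    "EvalReport",
    "pool_channels",
    "pool_multimodal",
    "match_events",
    "score",
    "crossover_run",
    "aggregate_reports",
]


@dataclass
class EvalReport:
    """Event-level counts and metrics for one detector on one recording."""

    tp_pred: int
    fp_pred: int
    detected_events: int
    missed_events: int
    ppv: float | None
    sensitivity: float | None
    f1: float | None
    mape: float | None = None
    condition: str = ""
    patient_id: str = ""
    undefined: tuple = ()

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _merge_annotated(intervals: list[AnomalyInterval], gap: int) -> list[AnomalyInterval]:
    if not intervals:
        return []
    ordered = sorted(intervals, key=lambda iv: (iv.start, iv.end))
    out: list[AnomalyInterval] = []
    for iv in ordered:
        if out and iv.start <= out[-1].end + gap:
            prev = out[-1]
            modality = prev.modality if prev.modality == iv.modality else "combined"
            out[-1] = AnomalyInterval(
                start=prev.start,
                end=max(prev.end, iv.end),
                peak_error=max(prev.peak_error, iv.peak_error),
                modality=modality,
                channel_id=prev.channel_id if prev.channel_id == iv.channel_id else "",
                provenance=prev.provenance | iv.provenance,
            )
        else:
            out.append(iv)
    return out


def pool_channels(per_channel_intervals, gap_tolerance: int = 0) -> list[AnomalyInterval]:
    """Union-merge detections across channels of one recording.

    ``per_channel_intervals`` is an iterable of per-channel interval lists
    (or a dict keyed by channel id). All inputs must share a time base.
    """
    if isinstance(per_channel_intervals, dict):
        groups = list(per_channel_intervals.values())
    else:
        groups = list(per_channel_intervals)
    flat = [iv for group in groups for iv in group]
    return _merge_annotated(flat, gap_tolerance)


def pool_multimodal(seeg_intervals: list[AnomalyInterval],
                    video_intervals: list[AnomalyInterval],
                    fs: float, fps: float,
                    gap_tolerance: int = 0) -> list[AnomalyInterval]:
    """Union of SEEG-time detections with frame-time video detections.

    Video intervals are rescaled from frames to samples via ``fs / fps``
    before the union-merge; each pooled interval retains the set of
    modalities that contributed. Union can only add coverage, which is why
    pooling never lowers sensitivity.
    """
    if fs <= 0 or fps <= 0:
        raise ParameterError("fs and fps must be positive")
    factor = fs / fps
    video_samples = [iv.rescaled(factor) for iv in video_intervals]
    return _merge_annotated(list(seeg_intervals) + video_samples, gap_tolerance)


def _truth_array(truth) -> np.ndarray:
    if isinstance(truth, EventLabelSet):
        return truth.intervals
    return intervals_to_array(truth)


def match_events(predicted, truth, rule: str = "overlap",
                 iou_threshold: float = 0.1) -> tuple[int, int, int, int]:
    """Count (tp_pred, fp_pred, detected_events, missed_events).

    Any-overlap (default): a prediction is a TP if it overlaps any truth
    event; one long prediction covering two truth events yields one TP and
    two detected events. The 'iou' rule requires intersection-over-union of
    at least ``iou_threshold`` instead.
    """
    pred = intervals_to_array(predicted)
    tr = _truth_array(truth)
    if pred.shape[0] == 0:
        return 0, 0, 0, int(tr.shape[0])

    def matches(p, t) -> bool:
        inter = min(p[1], t[1]) - max(p[0], t[0])
        if inter <= 0:
            return False
        if rule == "overlap":
            return True
        if rule == "iou":
            union = max(p[1], t[1]) - min(p[0], t[0])
            return inter / union >= iou_threshold
        raise ParameterError(f"unknown matching rule {rule!r}")

    tp_pred = sum(1 for p in pred if any(matches(p, t) for t in tr))
    detected = sum(1 for t in tr if any(matches(p, t) for p in pred))
    return tp_pred, int(pred.shape[0]) - tp_pred, detected, int(tr.shape[0]) - detected


def score(predicted, truth, mape_value: float | None = None,
          condition: str = "", patient_id: str = "",
          rule: str = "overlap", iou_threshold: float = 0.1) -> EvalReport:
    """Event-level PPV / sensitivity / F1 for one detector on one recording."""
    tp, fp, detected, missed = match_events(predicted, truth, rule=rule,
                                            iou_threshold=iou_threshold)
    undefined = []
    ppv = sens = f1 = None
    if tp + fp > 0:
        ppv = 100.0 * tp / (tp + fp)
    else:
        undefined.append("ppv")
    if detected + missed > 0:
        sens = 100.0 * detected / (detected + missed)
    else:
        undefined.append("sensitivity")
    if ppv is not None and sens is not None and (ppv + sens) > 0:
        p, s = ppv / 100.0, sens / 100.0
        f1 = 2.0 * p * s / (p + s)
    else:
        undefined.append("f1")
    return EvalReport(tp_pred=tp, fp_pred=fp, detected_events=detected,
                      missed_events=missed, ppv=ppv, sensitivity=sens, f1=f1,
                      mape=mape_value, condition=condition,
                      patient_id=patient_id, undefined=tuple(undefined))


def crossover_run(model, recording, truth,
                  forecast_config: ForecastConfig = ForecastConfig(),
                  split: SplitSpec = SplitSpec(),
                  dynamic: DynamicConfig = DynamicConfig(),
                  span: int | None = None) -> tuple[EvalReport, object]:
    """Apply a (foreign) patient's model to another patient's recording.

    All other conditions — splitting, smoothing, dynamic thresholding, error
    pruning — are identical to the ordinary detection path. The recording
    must share the sampling rate the model was trained at.

    Returns ``(report, detection_result)``.
    """
    trained_fs = getattr(model, "trained_on", {}).get("fs")
    if trained_fs is not None and trained_fs != recording.fs:
        raise ParameterError(
            f"model trained at fs={trained_fs} applied to recording at fs={recording.fs}"
        )
    result = detect_on_series(recording, model=model,
                              forecast_config=forecast_config, split=split,
                              dynamic=dynamic, span=span)
    report = score(result.intervals, truth, mape_value=result.mape,
                   condition="crossover", patient_id=recording.patient_id)
    return report, result


_METRICS = ("ppv", "sensitivity", "f1", "mape")


def aggregate_reports(reports: list[EvalReport]) -> pd.DataFrame:
    """Per-condition mean and SEM of each metric (undefined values excluded).

    Returns a table with one row per condition and columns
    ``<metric>_mean``, ``<metric>_sem``, ``<metric>_n``; SEM uses the sample
    standard deviation and is NaN for a single report.
    """
    if not reports:
        raise ParameterError("at least one report is required")
    rows = {}
    by_condition: dict[str, list[EvalReport]] = {}
    for r in reports:
        by_condition.setdefault(r.condition, []).append(r)
    for condition, group in by_condition.items():
        row = {}
        for metric in _METRICS:
            values = [getattr(r, metric) for r in group
                      if getattr(r, metric) is not None]
            n = len(values)
            row[f"{metric}_n"] = n
            row[f"{metric}_mean"] = float(np.mean(values)) if n else np.nan
            row[f"{metric}_sem"] = (
                float(np.std(values, ddof=1) / np.sqrt(n)) if n > 1 else np.nan
            )
        rows[condition] = row
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "condition"
    return table
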