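"""Per-channel self-supervised sequence forecasting and error series.

A forecaster learns to predict the next ``horizon`` values of a scaled
channel from the preceding ``history_window`` values, trained only on the
(unlabeled) training segment. On the test segment, rolling one-step
predictions are compared with the observed signal; the absolute differences,
smoothed with an exponentially weighted moving average, form the
``SmoothedErrorSeries`` that the thresholding stage classifies.

Two interchangeable forecasters satisfy the same contract:

* :class:`LSTMForecaster` — a single-layer LSTM (default 80 hidden units)
  with a dense head, trained with Adam on MSE, dropout 0.3, a chronological
  20% validation split, and early stopping (min improvement 0.003,
  patience 5, at most 35 epochs).
* :class:`ARForecaster` — a deterministic least-squares AR(p) baseline, used
  where neural training would be needlessly slow (large benchmarks, tests of
  downstream stages).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from ._nn import Adam, LSTMCore, mse
from .core import ChannelSeries, DataError, ParameterError

__all__ = [
    "ForecastConfig",
    "SmoothedErrorSeries",
    "TrainingDivergedError",
    "UndefinedMetricError",
    "early_stop_epoch",
    "ARForecaster",
    "LSTMForecaster",
    "train_forecaster",
    "fit_ar_baseline",
    "forecast",
    "smoothed_error",
    "default_span",
    "mape",
    "save_model",
    "load_model",
]

logger = logging.getLogger("ictaldetect")

_SCHEMA_VERSION = 1


class TrainingDivergedError(RuntimeError):
    """Training produced a non-finite loss."""


class UndefinedMetricError(ValueError):
    """A metric's denominator set is empty (e.g. all samples below the floor)."""


@dataclass(frozen=True)
class ForecastConfig:
    """Training regimen and forecasting geometry.

    ``history_window`` (l_b) and ``horizon`` (l_f) set the rolling prediction
    geometry; the remaining fields are the training regimen: up to 35 epochs,
    early stopping when 5 consecutive epochs fail to improve the validation
    MSE by at least 0.003, dropout 0.3, Adam, a chronological 20% validation
    split, and 80 hidden units.
    """

    hidden_units: int = 80
    max_epochs: int = 35
    early_stop_min_delta: float = 0.003
    early_stop_patience: int = 5
    dropout: float = 0.3
    validation_fraction: float = 0.2
    history_window: int = 250
    horizon: int = 1
    learning_rate: float = 3e-3
    batch_size: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.validation_fraction < 1.0):
            raise ParameterError("validation_fraction must lie in (0, 1)")
        if self.early_stop_patience < 1:
            raise ParameterError("patience must be >= 1")
        if self.history_window < 1 or self.horizon < 1:
            raise ParameterError("history_window and horizon must be >= 1")
        if not (0.0 <= self.dropout < 1.0):
            raise ParameterError("dropout must lie in [0, 1)")


@dataclass
class SmoothedErrorSeries:
    """Raw and EWMA-smoothed absolute prediction errors, aligned to forecast
    targets (element ``i`` corresponds to test sample ``history_window + i``)."""

    e_s: np.ndarray
    raw: np.ndarray
    smoothing_span: int
    fs: float | None = None
    source_channel: str = ""

    def __post_init__(self) -> None:
        self.e_s = np.asarray(self.e_s, dtype=float)
        self.raw = np.asarray(self.raw, dtype=float)
        if np.any(self.e_s < 0):
            raise DataError("smoothed errors must be nonnegative")

    def __len__(self) -> int:
        return int(self.e_s.size)


def early_stop_epoch(losses, min_delta: float = 0.003, patience: int = 5) -> int | None:
    """1-based epoch at which the early-stopping rule fires, or None.

    Each training iteration must decrease the loss by at least ``min_delta``
    relative to the previous iteration; after ``patience`` consecutive
    iterations without such a decrease the rule fires at the last of them.
    """
    losses = list(losses)
    bad = 0
    for idx in range(1, len(losses)):
        if losses[idx] <= losses[idx - 1] - min_delta:
            bad = 0
        else:
            bad += 1
            if bad >= patience:
                return idx + 1
    return None


def _windows(values: np.ndarray, l_b: int, l_f: int) -> tuple[np.ndarray, np.ndarray]:
    """All (history, future) training pairs from a 1-D sequence."""
    n = values.size
    n_pairs = n - l_b - l_f + 1
    if n_pairs < 1:
        raise ParameterError(
            f"sequence of {n} samples too short for history {l_b} + horizon {l_f}"
        )
    X = sliding_window_view(values, l_b)[:n_pairs]
    Y = sliding_window_view(values[l_b:], l_f)[:n_pairs]
    return X, Y


class ARForecaster:
    """Deterministic autoregressive baseline fit by ordinary least squares.

    Satisfies the same rolling-forecast contract as the neural model; its
    multi-step predictions are produced recursively from the fitted one-step
    coefficients.
    """

    kind = "ar"

    def __init__(self, order: int = 16, history_window: int = 250, horizon: int = 1):
        if order < 1:
            raise ParameterError("AR order must be >= 1")
        if history_window < order:
            raise ParameterError("history_window must be >= AR order")
        self.order = order
        self.history_window = history_window
        self.horizon = horizon
        self.intercept = 0.0
        self.coefs = np.zeros(order)  # coefs[j] multiplies y[t-1-j]
        self.trained_on: dict = {}

    def fit(self, values: np.ndarray) -> "ARForecaster":
        values = np.asarray(values, dtype=float)
        X, Y = _windows(values, self.order, 1)
        design = np.column_stack([np.ones(X.shape[0]), X[:, ::-1]])
        beta, *_ = np.linalg.lstsq(design, Y[:, 0], rcond=None)
        self.intercept = float(beta[0])
        self.coefs = beta[1:]
        return self

    def predict_windows(self, W: np.ndarray) -> np.ndarray:
        W = np.asarray(W, dtype=float)
        out = np.empty((W.shape[0], self.horizon))
        hist = W[:, -self.order:][:, ::-1].copy()  # most recent lag first
        for h in range(self.horizon):
            pred = self.intercept + hist @ self.coefs
            out[:, h] = pred
            if h + 1 < self.horizon:
                hist = np.column_stack([pred, hist[:, :-1]])
        return out


class LSTMForecaster:
    """Single-layer LSTM forecaster with dense head (numpy implementation)."""

    kind = "lstm"

    def __init__(self, config: ForecastConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.core = LSTMCore(d_in=1, hidden=config.hidden_units,
                             d_out=config.horizon, rng=rng,
                             dropout=config.dropout)
        self.training_history: list[dict] = []
        self.trained_on: dict = {}

    @property
    def history_window(self) -> int:
        return self.config.history_window

    @property
    def horizon(self) -> int:
        return self.config.horizon

    def predict_windows(self, W: np.ndarray) -> np.ndarray:
        W = np.asarray(W, dtype=float)
        return self.core.predict(W[:, :, None])

    # -- training ------------------------------------------------------------
    def fit(self, values: np.ndarray) -> "LSTMForecaster":
        cfg = self.config
        X, Y = _windows(np.asarray(values, dtype=float), cfg.history_window,
                        cfg.horizon)
        n = X.shape[0]
        n_val = max(1, int(round(n * cfg.validation_fraction)))
        if n - n_val < 1:
            raise ParameterError("training sequence too short for validation split")
        # chronological split: the final windows validate
        X_tr, Y_tr = X[: n - n_val], Y[: n - n_val]
        X_val, Y_val = X[n - n_val:], Y[n - n_val:]

        rng = np.random.default_rng(cfg.seed + 1)
        opt = Adam(self.core.params, lr=cfg.learning_rate)
        val_losses: list[float] = []
        best_val = np.inf
        best_params: dict | None = None
        for epoch in range(1, cfg.max_epochs + 1):
            order = rng.permutation(X_tr.shape[0])
            epoch_loss = 0.0
            for lo in range(0, order.size, cfg.batch_size):
                idx = order[lo: lo + cfg.batch_size]
                xb = X_tr[idx][:, :, None]
                yb = Y_tr[idx]
                pred, ctx = self.core.forward(xb, train=True, rng=rng)
                diff = pred - yb
                loss = float(np.mean(diff ** 2))
                if not np.isfinite(loss):
                    raise TrainingDivergedError(
                        f"non-finite training loss at epoch {epoch}")
                epoch_loss += loss * idx.size
                dy = 2.0 * diff / diff.size
                grads = self.core.backward(dy, ctx)
                opt.step(grads)
            epoch_loss /= X_tr.shape[0]
            val_loss = mse(self.core.predict(X_val[:, :, None]), Y_val)
            if not np.isfinite(val_loss):
                raise TrainingDivergedError(f"non-finite validation loss at epoch {epoch}")
            val_losses.append(val_loss)
            self.training_history.append(
                {"epoch": epoch, "train_loss": epoch_loss, "val_loss": val_loss}
            )
            if val_loss < best_val:
                best_val = val_loss
                best_params = {k: v.copy() for k, v in self.core.params.items()}
            if early_stop_epoch(val_losses, cfg.early_stop_min_delta,
                                cfg.early_stop_patience) is not None:
                break
        if best_params is not None:  # keep the best-validation weights
            self.core.params.update(best_params)
        return self


def train_forecaster(train: ChannelSeries, config: ForecastConfig = ForecastConfig()
                     ) -> LSTMForecaster:
    """Train the neural forecaster on one channel's training segment."""
    model = LSTMForecaster(config)
    model.fit(train.values)
    model.trained_on = {"patient_id": train.patient_id,
                        "channel_id": train.channel_id, "fs": train.fs}
    return model


def fit_ar_baseline(train: ChannelSeries, order: int = 16,
                    history_window: int = 250, horizon: int = 1) -> ARForecaster:
    """Fit the deterministic AR(p) baseline on one channel's training segment."""
    model = ARForecaster(order=order, history_window=history_window, horizon=horizon)
    model.fit(train.values)
    model.trained_on = {"patient_id": train.patient_id,
                        "channel_id": train.channel_id, "fs": train.fs}
    return model


def forecast(model, test, chunk: int = 4096) -> np.ndarray:
    """Rolling one-step predictions aligned one-to-one with ``test[l_b:]``.

    For every position ``t >= l_b`` the model predicts the next ``horizon``
    values from the preceding ``l_b`` observed values; the first predicted
    value per step is retained (stride 1). Applying a model trained on one
    patient to another is allowed (crossover), but the provenance mismatch is
    logged.
    """
    values = np.asarray(getattr(test, "values", test), dtype=float)
    l_b = model.history_window
    if values.size <= l_b:
        raise ParameterError(
            f"test length {values.size} must exceed history window {l_b}"
        )
    trained_pid = getattr(model, "trained_on", {}).get("patient_id")
    test_pid = getattr(test, "patient_id", None)
    if trained_pid and test_pid and trained_pid != test_pid:
        logger.info("crossover forecast: model trained on %r applied to %r",
                    trained_pid, test_pid)
    W = sliding_window_view(values, l_b)[: values.size - l_b]
    preds = np.empty(W.shape[0])
    for lo in range(0, W.shape[0], chunk):
        preds[lo: lo + chunk] = model.predict_windows(W[lo: lo + chunk])[:, 0]
    return preds


def default_span(n: int) -> int:
    """Default EWMA span: 1% of the error-series length (at least 1)."""
    return max(1, int(round(0.01 * n)))


def smoothed_error(actual, predicted, span: int | None = None,
                   fs: float | None = None, source_channel: str = ""
                   ) -> SmoothedErrorSeries:
    """Absolute error ``e = |actual - predicted|`` smoothed by an EWMA.

    The EWMA is the standard recursion with ``alpha = 2 / (span + 1)``
    (``span=1`` reproduces the raw errors exactly).
    """
    actual = np.asarray(actual, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if actual.shape != predicted.shape:
        raise ParameterError(
            f"length mismatch: actual {actual.shape} vs predicted {predicted.shape}"
        )
    if span is None:
        span = default_span(actual.size)
    if span < 1:
        raise ParameterError("span must be >= 1")
    raw = np.abs(actual - predicted)
    e_s = pd.Series(raw).ewm(span=span, adjust=False).mean().to_numpy()
    return SmoothedErrorSeries(e_s=e_s, raw=raw, smoothing_span=int(span),
                               fs=fs, source_channel=source_channel)


def mape(actual, predicted, denom_floor: float = 1e-3) -> float:
    """Mean absolute percentage error over samples with ``|actual| >= floor``.

    On signals scaled to [-1, 1] the denominator crosses zero, so samples
    below ``denom_floor`` are excluded rather than allowed to blow up the
    metric.
    """
    if denom_floor <= 0:
        raise ParameterError("denom_floor must be positive")
    actual = np.asarray(actual, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if actual.shape != predicted.shape:
        raise ParameterError("length mismatch between actual and predicted")
    mask = np.abs(actual) >= denom_floor
    if not mask.any():
        raise UndefinedMetricError("all samples fall below denom_floor")
    return float(np.mean(np.abs(actual[mask] - predicted[mask])
                         / np.abs(actual[mask])) * 100.0)


# -- serialization ------------------------------------------------------------

def save_model(model, path) -> None:
    """Serialize a forecaster (JSON, schema-versioned, lossless floats)."""
    payload = {"schema": _SCHEMA_VERSION, "kind": model.kind,
               "trained_on": getattr(model, "trained_on", {})}
    if model.kind == "lstm":
        payload["config"] = asdict(model.config)
        payload["params"] = {k: v.tolist() for k, v in model.core.params.items()}
        payload["training_history"] = model.training_history
    elif model.kind == "ar":
        payload["order"] = model.order
        payload["history_window"] = model.history_window
        payload["horizon"] = model.horizon
        payload["intercept"] = model.intercept
        payload["coefs"] = model.coefs.tolist()
    else:  # pragma: no cover
        raise ParameterError(f"unknown model kind {model.kind!r}")
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path):
    """Load a forecaster saved by :func:`save_model` (bit-identical forecasts)."""
    try:
        with open(path) as fh:
            payload = json.load(fh)
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise DataError(f"{path}: not a valid model file: {exc}") from exc
    if payload.get("schema") != _SCHEMA_VERSION:
        raise DataError(
            f"{path}: model schema {payload.get('schema')!r} not supported "
            f"(expected {_SCHEMA_VERSION})"
        )
    kind = payload.get("kind")
    if kind == "lstm":
        model = LSTMForecaster(ForecastConfig(**payload["config"]))
        for k, v in payload["params"].items():
            model.core.params[k] = np.asarray(v, dtype=float)
        model.training_history = payload.get("training_history", [])
        model.trained_on = payload.get("trained_on", {})
        return model
    if kind == "ar":
        model = ARForecaster(order=payload["order"],
                             history_window=payload["history_window"],
                             horizon=payload["horizon"])
        model.intercept = payload["intercept"]
        model.coefs = np.asarray(payload["coefs"], dtype=float)
        model.trained_on = payload.get("trained_on", {})
        return model
    raise DataError(f"{path}: unknown model kind {kind!r}")
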