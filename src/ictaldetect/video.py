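"""Video regularity scoring: frame autoencoder -> per-frame error -> s(t).

Grayscale frames are stacked into short temporal volumes and reconstructed by
a seeded dense autoencoder (two encoder and two mirrored decoder layers,
tanh hidden units, Adam on MSE). The per-frame reconstruction error — all
pixel-wise errors summed — is min-max normalized into an abnormality score
``a(t) = (e(t) - min e) / max e`` and the regularity score ``s(t) = 1 - a(t)``.
Regular motion reconstructs well (s near 1); seizures, and nuisance activity
like nurse visits, drive s down. The regularity series then enters the very
same forecasting/thresholding path as an SEEG channel.

Without a deep-learning framework in the environment, the reference
convolutional-LSTM autoencoder is replaced by this desk-scale dense
spatiotemporal autoencoder; the regularity-score math and everything
downstream are unchanged (see docs/methods.md).
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import imageio.v3 as iio
import numpy as np
from scipy import ndimage

from ._nn import MLP, Adam
from .core import ChannelSeries, DataError, ParameterError
from .detect import detect_on_series
from .forecast import ForecastConfig
from .preprocess import SplitSpec
from .threshold import DynamicConfig

__all__ = [
    "FrameSequence",
    "AutoencoderConfig",
    "RegularitySeries",
    "load_frames",
    "frames_from_array",
    "train_autoencoder",
    "VideoAutoencoder",
    "frame_errors",
    "regularity_score",
    "detect_video_anomalies",
]


@dataclass
class FrameSequence:
    """Ordered grayscale frames, intensities in [0, 1], uniform shape."""

    frames: np.ndarray  # (n, H, W)
    fps: float = 30.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise DataError("frames must be a (n, height, width) array")
        if not (self.fps > 0):
            raise ParameterError("fps must be positive")

    def __len__(self) -> int:
        return int(self.frames.shape[0])

    @property
    def frame_shape(self) -> tuple[int, int]:
        return (int(self.frames.shape[1]), int(self.frames.shape[2]))


@dataclass(frozen=True)
class AutoencoderConfig:
    """Desk-scale autoencoder configuration.

    ``temporal_depth`` frames form one input volume; ``hidden`` are the two
    encoder layer widths (the decoder mirrors them). ``error_kind`` fixes the
    per-pixel error convention ('squared' or 'absolute') used when summing
    frame errors.
    """

    temporal_depth: int = 10
    input_size: tuple[int, int] = (64, 64)
    hidden: tuple[int, int] = (256, 64)
    epochs: int = 30
    batch_size: int = 16
    learning_rate: float = 1e-3
    error_kind: str = "squared"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.temporal_depth < 1:
            raise ParameterError("temporal_depth must be >= 1")
        if self.error_kind not in ("squared", "absolute"):
            raise ParameterError("error_kind must be 'squared' or 'absolute'")
        if len(self.hidden) != 2:
            raise ParameterError("exactly two encoder layer widths expected")


@dataclass
class RegularitySeries:
    """Per-frame error e(t), abnormality a(t) in [0,1], regularity s(t) = 1 - a(t)."""

    e_t: np.ndarray
    a_t: np.ndarray
    s_t: np.ndarray
    fps: float = 30.0

    def __len__(self) -> int:
        return int(self.s_t.size)


_FRAME_EXTS = (".tiff", ".tif", ".png", ".jpg", ".jpeg", ".bmp")


def load_frames(directory, target_size: tuple[int, int] | None = None,
                stride: int = 1, fps: float = 30.0,
                strict: bool = True) -> FrameSequence:
    """Load frames from a directory (lexicographic filename order = time).

    Frames are converted to grayscale, optionally resized, and scaled to
    [0, 1]. ``stride`` keeps every stride-th frame. Unreadable frames raise in
    strict mode and are skipped with a warning otherwise.
    """
    names = sorted(
        f for f in os.listdir(directory)
        if os.path.splitext(f)[1].lower() in _FRAME_EXTS
    )
    if not names:
        raise DataError(f"{directory}: no frame images found")
    names = names[::stride]
    frames = []
    for name in names:
        path = os.path.join(directory, name)
        try:
            img = np.asarray(iio.imread(path), dtype=float)
        except Exception as exc:
            if strict:
                raise DataError(f"unreadable frame {path}: {exc}") from exc
            import warnings

            warnings.warn(f"skipping unreadable frame {path}: {exc}", stacklevel=2)
            continue
        if img.ndim == 3:
            img = img.mean(axis=2)
        if img.max() > 1.0:
            img = img / 255.0
        if target_size is not None and img.shape != tuple(target_size):
            zoom = (target_size[0] / img.shape[0], target_size[1] / img.shape[1])
            img = ndimage.zoom(img, zoom, order=1)
            img = img[: target_size[0], : target_size[1]]
        frames.append(np.clip(img, 0.0, 1.0))
    if not frames:
        raise DataError(f"{directory}: no readable frames")
    if len({f.shape for f in frames}) != 1:
        raise DataError("frames have mixed shapes; pass target_size to resize")
    return FrameSequence(frames=np.stack(frames), fps=fps / stride)


def frames_from_array(frames: np.ndarray, fps: float = 30.0) -> FrameSequence:
    """Wrap an in-memory (n, H, W) array, clipping intensities to [0, 1]."""
    return FrameSequence(frames=np.clip(np.asarray(frames, dtype=float), 0, 1),
                         fps=fps)


class VideoAutoencoder:
    """Dense spatiotemporal autoencoder over flattened frame volumes."""

    def __init__(self, config: AutoencoderConfig):
        self.config = config
        d = config.temporal_depth * config.input_size[0] * config.input_size[1]
        sizes = [d, config.hidden[0], config.hidden[1],
                 config.hidden[0], d]
        self._rng = np.random.default_rng(config.seed)
        self.net = MLP(sizes, self._rng)
        self.loss_history: list[float] = []

    @property
    def temporal_depth(self) -> int:
        return self.config.temporal_depth

    def _check(self, volumes: np.ndarray) -> np.ndarray:
        volumes = np.asarray(volumes, dtype=float)
        expected = (self.config.temporal_depth, *self.config.input_size)
        if volumes.shape[1:] != expected:
            raise DataError(
                f"volume shape {volumes.shape[1:]} does not match config {expected}"
            )
        return volumes

    def fit(self, volumes: np.ndarray) -> "VideoAutoencoder":
        volumes = self._check(volumes)
        X = volumes.reshape(volumes.shape[0], -1)
        opt = Adam(self.net.params, lr=self.config.learning_rate)
        for _ in range(self.config.epochs):
            order = self._rng.permutation(X.shape[0])
            epoch_loss = 0.0
            for lo in range(0, order.size, self.config.batch_size):
                idx = order[lo: lo + self.config.batch_size]
                xb = X[idx]
                pred, acts = self.net.forward(xb)
                diff = pred - xb
                epoch_loss += float(np.mean(diff ** 2)) * idx.size
                grads = self.net.backward(2.0 * diff / diff.size, acts)
                opt.step(grads)
            self.loss_history.append(epoch_loss / X.shape[0])
        return self

    def reconstruct(self, volumes: np.ndarray) -> np.ndarray:
        volumes = self._check(volumes)
        flat = volumes.reshape(volumes.shape[0], -1)
        return self.net.predict(flat).reshape(volumes.shape)


def _volumes(frames: FrameSequence, depth: int, stride: int) -> np.ndarray:
    n = len(frames)
    if n < depth:
        raise ParameterError(f"{n} frames < temporal_depth {depth}")
    starts = list(range(0, n - depth + 1, stride))
    if starts[-1] != n - depth:
        starts.append(n - depth)
    return np.stack([frames.frames[s: s + depth] for s in starts]), starts


def train_autoencoder(frames: FrameSequence, config: AutoencoderConfig = AutoencoderConfig()
                      ) -> VideoAutoencoder:
    """Train the autoencoder on non-overlapping volumes of the sequence."""
    if frames.frame_shape != tuple(config.input_size):
        raise DataError(
            f"frame shape {frames.frame_shape} does not match config "
            f"input_size {tuple(config.input_size)}"
        )
    volumes, _ = _volumes(frames, config.temporal_depth, config.temporal_depth)
    return VideoAutoencoder(config).fit(volumes)


def frame_errors(model, frames: FrameSequence, error_kind: str | None = None,
                 chunk: int = 64) -> np.ndarray:
    """Per-frame summed pixel-wise reconstruction error e(t).

    Stride-1 volumes cover the sequence; each frame's per-pixel errors are
    averaged over every volume containing it, then summed over pixels. The
    per-pixel convention ('squared' default, or 'absolute') comes from the
    model config unless overridden. ``model`` needs only ``temporal_depth``
    and ``reconstruct`` — test stubs plug in here.
    """
    depth = model.temporal_depth
    kind = error_kind or getattr(getattr(model, "config", None), "error_kind", "squared")
    if kind not in ("squared", "absolute"):
        raise ParameterError("error_kind must be 'squared' or 'absolute'")
    volumes, starts = _volumes(frames, depth, 1)
    n = len(frames)
    sums = np.zeros(n)
    counts = np.zeros(n)
    for lo in range(0, volumes.shape[0], chunk):
        batch = volumes[lo: lo + chunk]
        recon = model.reconstruct(batch)
        err = (batch - recon) ** 2 if kind == "squared" else np.abs(batch - recon)
        per_frame = err.sum(axis=(2, 3))  # (B, depth) summed over pixels
        for j, s in enumerate(starts[lo: lo + chunk]):
            sums[s: s + depth] += per_frame[j]
            counts[s: s + depth] += 1.0
    return sums / counts


def regularity_score(e_t, fps: float = 30.0) -> RegularitySeries:
    """Min-max normalize frame errors into abnormality/regularity scores.

    ``a(t) = (e(t) - min e) / max e`` and ``s(t) = 1 - a(t)``; a constant (or
    all-zero) error series yields s = 1 everywhere. The score is invariant to
    positive rescaling of the errors.
    """
    e_t = np.asarray(e_t, dtype=float)
    if e_t.size < 1:
        raise ParameterError("e_t must contain at least one value")
    if np.any(e_t < 0):
        raise DataError("frame errors must be nonnegative")
    emax = float(np.max(e_t))
    if emax == 0.0:
        a = np.zeros_like(e_t)
    else:
        a = (e_t - float(np.min(e_t))) / emax
    return RegularitySeries(e_t=e_t, a_t=a, s_t=1.0 - a, fps=fps)


def detect_video_anomalies(scores, fps: float = 30.0,
                           forecaster: str = "ar",
                           forecast_config: ForecastConfig | None = None,
                           dynamic: DynamicConfig | None = None,
                           split: SplitSpec = SplitSpec(),
                           ar_order: int = 8,
                           channel_id: str = "video"):
    """Run the shared detection path on a regularity-score series.

    ``scores`` may be a :class:`RegularitySeries` or a plain array of s(t).
    Returned intervals are frame-indexed and carry ``modality='video'``; the
    schema is identical to SEEG detections, which is what makes multimodal
    pooling a plain union.
    """
    s_t = np.asarray(getattr(scores, "s_t", scores), dtype=float)
    if forecast_config is None:
        forecast_config = ForecastConfig(history_window=min(64, max(8, s_t.size // 20)))
    if dynamic is None:
        n_err = s_t.size - split.split_point(s_t.size) - forecast_config.history_window
        dynamic = DynamicConfig(window_size=max(10, min(2048, n_err // 4)))
    series = ChannelSeries(values=s_t, fs=fps, channel_id=channel_id)
    return detect_on_series(series, forecaster=forecaster,
                            forecast_config=forecast_config, ar_order=ar_order,
                            split=split, dynamic=dynamic, modality="video")
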