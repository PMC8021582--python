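"""Video regularity path: frames, autoencoder, scores, detection."""

import imageio.v3 as iio
import numpy as np
import pytest

from ictaldetect import (
    AutoencoderConfig,
    DataError,
    EventLabelSet,
    ParameterError,
    SplitSpec,
    detect_video_anomalies,
    frame_errors,
    frames_from_array,
    load_frames,
    regularity_score,
    train_autoencoder,
)
from ictaldetect.forecast import ForecastConfig
from ictaldetect.simulate import NuisanceSpec, gen_regularity_trace
from ictaldetect.threshold import DynamicConfig


@pytest.fixture()
def frame_dir(tmp_path, rng):
    for i in range(20):
        img = (rng.random((64, 64)) * 255).astype(np.uint8)
        iio.imwrite(tmp_path / f"frame_{i:04d}.png", img)
    return tmp_path


class TestLoadFrames:
    def test_fixture_loads_in_order(self, frame_dir):
        seq = load_frames(frame_dir)
        assert len(seq) == 20 and seq.frame_shape == (64, 64)
        assert seq.frames.min() >= 0.0 and seq.frames.max() <= 1.0

    def test_stride(self, frame_dir):
        assert len(load_frames(frame_dir, stride=2)) == 10

    def test_all_black(self, tmp_path):
        for i in range(5):
            iio.imwrite(tmp_path / f"f{i}.png", np.zeros((8, 8), dtype=np.uint8))
        seq = load_frames(tmp_path)
        assert np.all(seq.frames == 0.0)

    def test_resize(self, frame_dir):
        seq = load_frames(frame_dir, target_size=(32, 32))
        assert seq.frame_shape == (32, 32)

    def test_empty_dir_rejected(self, tmp_path):
        with pytest.raises(DataError):
            load_frames(tmp_path)


class TestAutoencoder:
    CFG = AutoencoderConfig(temporal_depth=5, input_size=(16, 16),
                            hidden=(64, 16), epochs=30, seed=0)

    @pytest.fixture()
    def static_frames(self, rng):
        frame = rng.random((16, 16)) * 0.5 + 0.25
        return frames_from_array(np.tile(frame, (40, 1, 1)))

    def test_converges_on_static_scene(self, static_frames):
        model = train_autoencoder(static_frames, self.CFG)
        assert model.loss_history[-1] < 0.1 * model.loss_history[0]

    def test_seeded_runs_are_identical(self, static_frames):
        m1 = train_autoencoder(static_frames, self.CFG)
        m2 = train_autoencoder(static_frames, self.CFG)
        assert m1.loss_history == m2.loss_history

    def test_too_few_frames_rejected(self, rng):
        frames = frames_from_array(rng.random((3, 16, 16)))
        with pytest.raises(ParameterError):
            train_autoencoder(frames, self.CFG)


class _StubModel:
    """Reconstruction stub with a fixed output and pinned error convention."""

    def __init__(self, mode, depth=5, error_kind="squared"):
        self.mode = mode
        self.temporal_depth = depth

        class _Cfg:
            pass

        self.config = _Cfg()
        self.config.error_kind = error_kind

    def reconstruct(self, volumes):
        if self.mode == "identity":
            return np.asarray(volumes).copy()
        return np.zeros_like(volumes)


class TestFrameErrors:
    def test_identity_stub_gives_zero(self, rng):
        frames = frames_from_array(rng.random((12, 8, 8)))
        e = frame_errors(_StubModel("identity"), frames)
        assert np.allclose(e, 0.0)

    def test_zeros_stub_closed_form(self):
        # N pixels at intensity 0.5: squared -> 0.25 N, absolute -> 0.5 N
        frames = frames_from_array(np.full((10, 8, 8), 0.5))
        n_pix = 64
        e_sq = frame_errors(_StubModel("zeros", error_kind="squared"), frames)
        assert np.allclose(e_sq, 0.25 * n_pix)
        e_abs = frame_errors(_StubModel("zeros", error_kind="absolute"), frames)
        assert np.allclose(e_abs, 0.5 * n_pix)

    def test_absolute_errors_are_homogeneous(self):
        e1 = frame_errors(_StubModel("zeros", error_kind="absolute"),
                          frames_from_array(np.full((10, 8, 8), 0.25)))
        e2 = frame_errors(_StubModel("zeros", error_kind="absolute"),
                          frames_from_array(np.full((10, 8, 8), 0.5)))
        assert np.allclose(e2, 2 * e1)


class TestRegularityScore:
    def test_endpoints(self):
        out = regularity_score([0.0, 10.0])
        assert np.allclose(out.a_t, [0, 1]) and np.allclose(out.s_t, [1, 0])

    def test_constant_errors_are_fully_regular(self):
        assert np.allclose(regularity_score([5.0, 5.0, 5.0]).s_t, 1.0)

    def test_hand_evaluated(self):
        out = regularity_score([2.0, 4.0, 10.0])
        assert np.allclose(out.a_t, [0.0, 0.2, 0.8])
        assert np.allclose(out.s_t, [1.0, 0.8, 0.2])

    def test_invariant_to_positive_rescaling(self, rng):
        e = rng.random(50) * 7
        assert np.allclose(regularity_score(e).a_t, regularity_score(3.5 * e).a_t)

    def test_bounds_and_min_abnormality(self, rng):
        out = regularity_score(rng.random(100) + 0.1)
        assert np.all((out.s_t >= 0) & (out.s_t <= 1))
        assert out.a_t.min() == 0.0 and out.s_t.max() == 1.0


class TestVideoDetection:
    FC = ForecastConfig(hidden_units=8, history_window=32, max_epochs=10, seed=0)

    def test_constant_scores_yield_no_anomalies(self):
        res = detect_video_anomalies(np.ones(4000), fps=30.0, forecaster="ar",
                                     dynamic=DynamicConfig(window_size=256))
        assert res.intervals == []

    def test_deep_drop_flagged_shallow_dip_depends_on_pruning(self):
        truth = EventLabelSet(np.array([[9000, 9450]]), fs=30.0,
                              source="synthetic-truth")
        trace, _ = gen_regularity_trace(
            600.0, 30.0, truth,
            NuisanceSpec(n_dips=1, dip_depth=0.3, dip_duration_s=(10, 10)),
            seed=3)
        results = {}
        for scope in ("both", "none"):
            res = detect_video_anomalies(
                trace, fps=30.0, forecaster="lstm", forecast_config=self.FC,
                dynamic=DynamicConfig(window_size=4096, step=2048,
                                      prune_scope=scope),
                split=SplitSpec())
            results[scope] = [(iv.start, iv.end) for iv in res.intervals]

        def hit(det):
            return any(s < 9450 and 9000 < e for s, e in det)

        # the deep (true-event) drop is flagged under both settings; the
        # pruned run keeps only it, the unpruned run also flags nuisance
        assert hit(results["both"]) and hit(results["none"])
        assert len(results["both"]) == 1
        assert len(results["none"]) > len(results["both"])

    def test_same_interval_schema_as_seeg(self):
        truth = EventLabelSet(np.array([[9000, 9450]]), fs=30.0,
                              source="synthetic-truth")
        trace, _ = gen_regularity_trace(600.0, 30.0, truth, seed=1)
        res = detect_video_anomalies(trace, fps=30.0, forecaster="lstm",
                                     forecast_config=self.FC,
                                     dynamic=DynamicConfig(window_size=4096),
                                     split=SplitSpec())
        for iv in res.intervals:
            assert iv.modality == "video"
            assert iv.start < iv.end and iv.peak_error >= 0


class TestFullVideoPath:
    def test_irregular_segment_detected_end_to_end(self, rng):
        # static scene with an injected segment of irregular motion; the
        # autoencoder is trained self-supervised on the regular head only
        base = np.tile(rng.random((16, 16)) * 0.5 + 0.25, (300, 1, 1))
        base += rng.normal(0, 0.01, base.shape)
        base[180:220] = rng.random((40, 16, 16))
        frames = frames_from_array(base, fps=30.0)
        cfg = AutoencoderConfig(temporal_depth=5, input_size=(16, 16),
                                hidden=(64, 16), epochs=30, seed=0)
        model = train_autoencoder(frames_from_array(base[:150], fps=30.0), cfg)
        e = frame_errors(model, frames)
        scores = regularity_score(e, fps=30.0)
        inside = scores.s_t[185:215]
        outside = np.concatenate([scores.s_t[:170], scores.s_t[230:]])
        assert inside.max() < 0.5  # deeply irregular throughout the segment
        assert outside.min() > 0.9  # regular elsewhere
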