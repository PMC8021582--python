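"""Forecasters, smoothed errors, MAPE, early stopping, serialization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ictaldetect import (
    ARForecaster,
    ChannelSeries,
    ForecastConfig,
    ParameterError,
    SplitSpec,
    early_stop_epoch,
    fit_ar_baseline,
    forecast,
    load_model,
    mape,
    save_model,
    smoothed_error,
    split_train_test,
    train_forecaster,
)
from ictaldetect._nn import LSTMCore, MLP
from ictaldetect.forecast import UndefinedMetricError


class _LastValueStub:
    """Identity-like forecaster: predicts the last seen value."""

    history_window = 2
    horizon = 1
    trained_on = {}

    def predict_windows(self, W):
        return np.asarray(W)[:, -1:]


class TestForecastContract:
    def test_stub_predicts_last_value(self):
        preds = forecast(_LastValueStub(), ChannelSeries([1.0, 2, 3, 4], fs=1))
        assert np.allclose(preds, [2.0, 3.0])

    def test_alignment_length(self, rng):
        model = _LastValueStub()
        for k in (1, 5, 100):
            series = ChannelSeries(rng.standard_normal(model.history_window + k), fs=1)
            assert forecast(model, series).size == k

    def test_test_shorter_than_history_rejected(self):
        with pytest.raises(ParameterError):
            forecast(_LastValueStub(), ChannelSeries([1.0, 2.0], fs=1))

    def test_crossover_application_is_allowed_and_logged(self, caplog, rng):
        train = ChannelSeries(rng.standard_normal(500), fs=100, patient_id="A")
        model = fit_ar_baseline(train, order=4, history_window=8)
        other = ChannelSeries(rng.standard_normal(100), fs=100, patient_id="B")
        with caplog.at_level("INFO", logger="ictaldetect"):
            preds = forecast(model, other)
        assert preds.size == 92
        assert any("crossover" in r.message for r in caplog.records)


class TestARBaseline:
    def test_recovers_ar_process(self, rng):
        # AR(2) process: the least-squares fit should predict near-optimally
        n = 4000
        x = np.zeros(n)
        eps = 0.05 * rng.standard_normal(n)
        for t in range(2, n):
            x[t] = 1.5 * x[t - 1] - 0.7 * x[t - 2] + eps[t]
        model = ARForecaster(order=2, history_window=10).fit(x[:3000])
        assert model.coefs == pytest.approx([1.5, -0.7], abs=0.05)
        preds = forecast(model, ChannelSeries(x[3000:], fs=1))
        resid = x[3010:] - preds
        assert np.std(resid) < 0.08  # close to the innovation scale

    def test_same_contract_as_neural(self, sinusoid_channel):
        # the deterministic AR(1) baseline plugs into the same rolling path;
        # the trained net's errors stay within 10x of that crude oracle
        train, test = split_train_test(sinusoid_channel, SplitSpec(0.5))
        ar1 = fit_ar_baseline(train, order=1, history_window=32)
        lstm = train_forecaster(
            train, ForecastConfig(hidden_units=8, history_window=32,
                                  max_epochs=3, seed=0))
        p_ar = forecast(ar1, test)
        p_nn = forecast(lstm, test)
        assert p_ar.shape == p_nn.shape
        err_ar = np.mean(np.abs(test.values[32:] - p_ar))
        err_nn = np.mean(np.abs(test.values[32:] - p_nn))
        assert err_ar > 1e-3  # AR(1) cannot track a sinusoid exactly
        assert err_nn < 10 * err_ar


class TestSmoothedError:
    def test_identity_gives_zeros(self):
        out = smoothed_error([1.0, 2, 3], [1.0, 2, 3], span=2)
        assert np.all(out.e_s == 0)

    def test_hand_stepped_ewma(self):
        # alpha = 2/(span+1) = 2/3, seeded with the first raw error
        out = smoothed_error([0, 0, 1, 0, 0], np.zeros(5), span=2)
        expected = [0, 0, 2 / 3, 2 / 9, 2 / 27]
        assert np.allclose(out.e_s, expected)
        assert np.all((out.e_s >= 0) & (out.e_s <= 1))

    def test_span_one_is_raw_error(self, rng):
        a = rng.standard_normal(50)
        p = rng.standard_normal(50)
        out = smoothed_error(a, p, span=1)
        assert np.array_equal(out.e_s, np.abs(a - p))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ParameterError):
            smoothed_error([1.0, 2], [1.0], span=1)

    @given(st.lists(st.floats(0, 10), min_size=3, max_size=30),
           st.lists(st.floats(0, 2), min_size=3, max_size=30),
           st.integers(1, 10))
    @settings(max_examples=80, deadline=None)
    def test_monotone_in_pointwise_error(self, base, bumps, span):
        # enlarging any |error| can never lower any smoothed value
        m = min(len(base), len(bumps))
        e1 = np.asarray(base[:m])
        e2 = e1 + np.asarray(bumps[:m])
        s1 = smoothed_error(e1, np.zeros(m), span=span).e_s
        s2 = smoothed_error(e2, np.zeros(m), span=span).e_s
        assert np.all(s2 - s1 >= -1e-12)


class TestMape:
    def test_identity(self):
        assert mape([1.0, 2, 3], [1.0, 2, 3]) == 0.0

    def test_arithmetic(self):
        assert mape([1, 2, 4], [1.1, 1.8, 4.4]) == pytest.approx(10.0)

    def test_floor_excludes_near_zero_samples(self):
        assert mape([0.0001, 1.0], [1.0, 1.0], denom_floor=0.001) == 0.0

    def test_all_below_floor_is_undefined(self):
        with pytest.raises(UndefinedMetricError):
            mape([1e-6, 1e-5], [1.0, 1.0], denom_floor=0.001)


class TestEarlyStopping:
    def test_pinned_trace_stops_at_epoch_six(self):
        trace = [1.0, 0.999, 0.998, 0.9975, 0.997, 0.9968]
        assert early_stop_epoch(trace, min_delta=0.003, patience=5) == 6

    def test_steady_improvement_never_stops(self):
        trace = [1.0 - 0.01 * k for k in range(35)]
        assert early_stop_epoch(trace, 0.003, 5) is None

    def test_flat_trace_stops_after_patience(self):
        assert early_stop_epoch([0.5] * 10, 0.003, 5) == 6

    def test_recovery_resets_patience(self):
        # a big drop at epoch 5 resets the counter
        trace = [1.0, 1.0, 1.0, 1.0, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5]
        assert early_stop_epoch(trace, 0.003, 5) == 10


class TestTraining:
    def test_constant_zero_series_fits_trivially(self):
        s = ChannelSeries(np.zeros(500), fs=100)
        model = train_forecaster(s, ForecastConfig(hidden_units=4,
                                                   history_window=16, seed=0))
        assert len(model.training_history) <= 35
        assert model.training_history[-1]["train_loss"] < 1e-4

    def test_training_is_deterministic(self, sinusoid_channel):
        train, _ = split_train_test(sinusoid_channel, SplitSpec(0.2))
        cfg = ForecastConfig(hidden_units=6, history_window=16, max_epochs=3, seed=9)
        m1 = train_forecaster(train, cfg)
        m2 = train_forecaster(train, cfg)
        assert m1.training_history == m2.training_history
        W = np.linspace(-1, 1, 16)[None, :]
        assert np.array_equal(m1.predict_windows(W), m2.predict_windows(W))

    def test_sequence_too_short_rejected(self):
        with pytest.raises(ParameterError):
            train_forecaster(ChannelSeries(np.zeros(20), fs=10),
                             ForecastConfig(history_window=64))


class TestGradients:
    def _check(self, params, loss_fn, grads, n_per_param=6, eps=1e-6, tol=1e-7):
        worst = 0.0
        for k, P in params.items():
            it = np.nditer(P, flags=["multi_index"])
            for _ in range(min(P.size, n_per_param)):
                idx = it.multi_index
                old = P[idx]
                P[idx] = old + eps
                lp = loss_fn()
                P[idx] = old - eps
                lm = loss_fn()
                P[idx] = old
                worst = max(worst, abs((lp - lm) / (2 * eps) - grads[k][idx]))
                it.iternext()
        assert worst < tol

    def test_lstm_backward_matches_finite_differences(self):
        g = np.random.default_rng(0)
        core = LSTMCore(d_in=1, hidden=4, d_out=2, rng=g, dropout=0.0)
        X = g.standard_normal((3, 6, 1))
        Y = g.standard_normal((3, 2))

        def loss():
            y, _ = core.forward(X)
            return float(np.mean((y - Y) ** 2))

        y, ctx = core.forward(X)
        grads = core.backward(2 * (y - Y) / y.size, ctx)
        self._check(core.params, loss, grads)

    def test_mlp_backward_matches_finite_differences(self):
        g = np.random.default_rng(1)
        net = MLP([5, 4, 3, 4, 5], g)
        X = g.standard_normal((4, 5))

        def loss():
            y, _ = net.forward(X)
            return float(np.mean((y - X) ** 2))

        y, acts = net.forward(X)
        grads = net.backward(2 * (y - X) / y.size, acts)
        self._check(net.params, loss, grads)


class TestSerialization:
    def test_ar_round_trip_bit_identical(self, rng, tmp_path):
        train = ChannelSeries(rng.standard_normal(400), fs=100, patient_id="A")
        model = fit_ar_baseline(train, order=6, history_window=12)
        path = tmp_path / "m.json"
        save_model(model, path)
        back = load_model(path)
        W = rng.standard_normal((5, 12))
        assert np.array_equal(model.predict_windows(W), back.predict_windows(W))
        assert back.trained_on["patient_id"] == "A"

    def test_lstm_round_trip_bit_identical(self, rng, tmp_path):
        train = ChannelSeries(np.sin(np.arange(600) / 5.0), fs=100)
        cfg = ForecastConfig(hidden_units=5, history_window=12, max_epochs=2, seed=3)
        model = train_forecaster(train, cfg)
        path = tmp_path / "m.json"
        save_model(model, path)
        back = load_model(path)
        W = rng.standard_normal((4, 12))
        assert np.array_equal(model.predict_windows(W), back.predict_windows(W))
        assert back.config == cfg

    def test_corrupted_file_rejected(self, tmp_path):
        path = tmp_path / "junk.json"
        path.write_bytes(b"\x00\x01not json")
        from ictaldetect import DataError

        with pytest.raises(DataError):
            load_model(path)

    def test_schema_mismatch_rejected(self, tmp_path):
        path = tmp_path / "old.json"
        path.write_text('{"schema": 99, "kind": "ar"}')
        from ictaldetect import DataError

        with pytest.raises(DataError, match="schema"):
            load_model(path)
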