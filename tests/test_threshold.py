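"""Dynamic thresholding: objective, grid search, detection, pruning, static."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ictaldetect.core import AnomalyInterval, ParameterError
from ictaldetect.threshold import (
    DynamicConfig,
    detect_anomalous_sequences,
    find_dynamic_threshold,
    prune_anomalies,
    static_threshold_detect,
    threshold_objective,
)


class TestObjective:
    def test_pinned_window_no_exceedance_at_z2(self):
        # mu = 2.8, population sigma = 3.6 -> eps = 10.0; nothing strictly above
        eps, obj, dec = threshold_objective([1, 1, 1, 1, 10], z=2, penalized=False)
        assert eps == pytest.approx(10.0)
        assert obj == 0.0

    def test_pinned_window_z1_unpenalized_and_penalized(self):
        eps, obj, dec = threshold_objective([1, 1, 1, 1, 10], z=1, penalized=False)
        assert eps == pytest.approx(6.4)
        assert obj == pytest.approx(1.8 / 2.8 + 3.6 / 3.6)
        assert dec.delta_mu == pytest.approx(1.8)
        assert dec.delta_sigma == pytest.approx(3.6)
        # penalty (n_above + n_runs^2) = (1 + 1) = 2
        _, obj_p, dec_p = threshold_objective([1, 1, 1, 1, 10], z=1, penalized=True)
        assert obj_p == pytest.approx(obj / 2.0)
        assert dec_p.n_anom_points == 1 and dec_p.n_anom_seqs == 1

    def test_all_equal_window_is_degenerate(self):
        eps, obj, dec = threshold_objective([3.0] * 20, z=2)
        assert obj == 0.0 and dec.no_anomaly

    def test_huge_z_gives_zero_objective(self):
        _, obj, _ = threshold_objective(np.arange(10.0), z=100)
        assert obj == 0.0

    def test_window_too_short(self):
        with pytest.raises(ParameterError):
            threshold_objective([1.0], z=2)

    @given(st.lists(st.floats(0, 100), min_size=5, max_size=50),
           st.floats(0, 8))
    @settings(max_examples=100, deadline=None)
    def test_delta_mu_nonnegative_for_nonneg_z(self, values, z):
        # excluding above-threshold values can never raise the mean
        _, _, dec = threshold_objective(values, z=z)
        assert dec.delta_mu >= -1e-12


class TestGridSearch:
    def test_tie_breaks_toward_larger_z(self):
        # z in {0.5, 1.0} exclude the same single point -> identical objective
        cfg = DynamicConfig(window_size=10, z_grid=(0.5, 1.0))
        dec = find_dynamic_threshold([1, 1, 1, 1, 10], cfg)
        assert dec.z == 1.0

    def test_degenerate_window_flags_no_anomaly(self):
        dec = find_dynamic_threshold([2.0] * 30, DynamicConfig(window_size=10))
        assert dec.no_anomaly and dec.epsilon == pytest.approx(2.0)

    def test_spike_dominates_noise(self):
        # the chosen threshold isolates a gross outlier from N(0,1) noise
        hits = 0
        cfg = DynamicConfig(window_size=10, z_grid=tuple(np.arange(2.0, 10.5, 0.5)))
        for seed in range(100):
            g = np.random.default_rng(seed)
            w = np.abs(g.standard_normal(150))
            w[g.integers(0, 150)] = 50.0
            dec = find_dynamic_threshold(w, cfg)
            exceed = np.flatnonzero(w > dec.epsilon)
            if dec.epsilon < 50 and exceed.size == 1 and w[exceed[0]] == 50.0:
                hits += 1
        assert hits >= 95


class TestDetect:
    def test_single_spike_block_yields_one_interval(self):
        e_s = np.zeros(512)
        e_s[100:110] = 5.0
        cfg = DynamicConfig(window_size=64, step=32)
        out = detect_anomalous_sequences(e_s, cfg)
        assert len(out) == 1
        assert out[0].start <= 100 and out[0].end >= 110
        assert out[0].peak_error == 5.0

    def test_constant_series_yields_nothing(self):
        assert detect_anomalous_sequences(np.full(300, 1.5),
                                          DynamicConfig(window_size=64)) == []

    def test_interval_schema(self, rng):
        e_s = np.abs(rng.standard_normal(1000))
        e_s[400:420] += 30
        out = detect_anomalous_sequences(e_s, DynamicConfig(window_size=128))
        starts = [iv.start for iv in out]
        assert starts == sorted(starts)
        for a, b in zip(out, out[1:]):
            assert a.end <= b.start
        for iv in out:
            assert 0 <= iv.start < iv.end <= e_s.size

    def test_series_shorter_than_window_errors(self):
        with pytest.raises(ParameterError):
            detect_anomalous_sequences(np.ones(50), DynamicConfig(window_size=64))


def _iv(start, end, peak):
    return AnomalyInterval(start=start, end=end, peak_error=peak)


class TestPrune:
    def test_hand_stepped_example(self):
        # peaks 100, 40, 38 with nominal outside max 37 and p = 0.10:
        # drops 0.60, 0.05, 0.026 -> only the peak-100 interval survives
        e_s = np.zeros(100)
        e_s[10] = 100.0
        e_s[40] = 40.0
        e_s[70] = 38.0
        e_s[90] = 37.0
        ivs = [_iv(10, 11, 100.0), _iv(40, 41, 40.0), _iv(70, 71, 38.0)]
        kept = prune_anomalies(ivs, e_s, p=0.10)
        assert [iv.peak_error for iv in kept] == [100.0]

    def test_p_zero_keeps_strictly_decreasing_peaks(self):
        e_s = np.zeros(100)
        e_s[[10, 40, 70]] = [9.0, 6.0, 3.0]
        ivs = [_iv(10, 11, 9.0), _iv(40, 41, 6.0), _iv(70, 71, 3.0)]
        assert len(prune_anomalies(ivs, e_s, p=0.0)) == 3

    def test_empty_input(self):
        assert prune_anomalies([], np.ones(10), p=0.1) == []

    def test_no_sufficient_drop_reclassifies_all(self):
        e_s = np.zeros(50)
        e_s[[5, 15]] = [10.0, 9.5]
        e_s[30] = 9.2  # nominal max close under the smallest peak
        ivs = [_iv(5, 6, 10.0), _iv(15, 16, 9.5)]
        assert prune_anomalies(ivs, e_s, p=0.10) == []

    @given(st.lists(st.floats(0.1, 100), min_size=1, max_size=8, unique=True),
           st.floats(0.0, 0.5), st.floats(0.0, 0.5),
           st.floats(0.0, 0.99))
    @settings(max_examples=100, deadline=None)
    def test_output_subset_and_monotone_in_p(self, peaks, p1, p2, nominal_frac):
        lo, hi = sorted((p1, p2))
        e_s = np.zeros(10 * len(peaks) + 10)
        e_s[-1] = nominal_frac * min(peaks)  # background just below the peaks
        ivs = []
        for k, pk in enumerate(peaks):
            e_s[10 * k + 5] = pk
            ivs.append(_iv(10 * k + 5, 10 * k + 6, pk))
        kept_lo = {iv.start for iv in prune_anomalies(ivs, e_s, p=lo)}
        kept_hi = {iv.start for iv in prune_anomalies(ivs, e_s, p=hi)}
        assert kept_hi <= kept_lo <= {iv.start for iv in ivs}


class TestStatic:
    def test_single_outlier_below_threshold_n4(self):
        # mu 25, population sigma 43.3 -> threshold ~111.6: nothing flagged
        assert static_threshold_detect(np.array([0, 0, 0, 100.0])) == []

    def test_single_outlier_flagged_n10(self):
        # mu 10, sigma 30 -> threshold 70 -> run [9, 10)
        out = static_threshold_detect(np.array([0.0] * 9 + [100.0]))
        assert [(iv.start, iv.end) for iv in out] == [(9, 10)]

    def test_gaussian_tail_fraction(self):
        g = np.random.default_rng(7)
        x = g.standard_normal(100_000)
        out = static_threshold_detect(x, k=2.0)
        flagged = sum(iv.end - iv.start for iv in out)
        # one-sided tail beyond 2 sigma ~ 2.28%
        assert flagged / x.size == pytest.approx(0.0228, abs=0.004)

    def test_constant_series(self):
        assert static_threshold_detect(np.ones(100)) == []
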