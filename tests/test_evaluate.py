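"""Pooling, event matching, scoring, aggregation, crossover contract."""

import numpy as np
import pytest

from ictaldetect import (
    AnomalyInterval,
    ChannelSeries,
    EventLabelSet,
    ParameterError,
    aggregate_reports,
    crossover_run,
    match_events,
    pool_channels,
    pool_multimodal,
    score,
)


def _iv(start, end, modality="seeg", peak=1.0):
    return AnomalyInterval(start=start, end=end, peak_error=peak, modality=modality)


class TestPooling:
    def test_union_merge_across_channels(self):
        pooled = pool_channels({"a": [_iv(0, 10)], "b": [_iv(5, 20)]})
        assert [(p.start, p.end) for p in pooled] == [(0, 20)]

    def test_disjoint_intervals_kept(self):
        pooled = pool_channels([[_iv(0, 10)], [_iv(110, 120)]], gap_tolerance=0)
        assert len(pooled) == 2

    def test_gap_tolerance_merges_near_neighbors(self):
        pooled = pool_channels([[_iv(0, 10)], [_iv(15, 20)]], gap_tolerance=10)
        assert [(p.start, p.end) for p in pooled] == [(0, 20)]

    def test_empty(self):
        assert pool_channels({}) == []

    def test_multimodal_union_with_time_base_conversion(self):
        # fs == fps so frames and samples coincide
        pooled = pool_multimodal([_iv(100, 200, "seeg")],
                                 [_iv(150, 300, "video")], fs=30.0, fps=30.0)
        assert [(p.start, p.end) for p in pooled] == [(100, 300)]
        assert pooled[0].provenance == {"seeg", "video"}

    def test_multimodal_rescales_frames_to_samples(self):
        pooled = pool_multimodal([], [_iv(30, 60, "video")], fs=256.0, fps=30.0)
        assert (pooled[0].start, pooled[0].end) == (256, 512)

    def test_video_only_event_survives_pooling(self):
        pooled = pool_multimodal([_iv(0, 10, "seeg")], [_iv(500, 600, "video")],
                                 fs=30.0, fps=30.0)
        assert len(pooled) == 2

    def test_both_empty(self):
        assert pool_multimodal([], [], fs=256.0, fps=30.0) == []


class TestMatching:
    def test_overlap_is_tp(self):
        assert match_events([(10, 20)], [(15, 25)]) == (1, 0, 1, 0)

    def test_disjoint_is_fp_and_miss(self):
        assert match_events([(0, 5)], [(15, 25)]) == (0, 1, 0, 1)

    def test_one_prediction_covering_two_events(self):
        tp, fp, det, miss = match_events([(10, 30)], [(12, 14), (20, 22)])
        assert (tp, fp, det, miss) == (1, 0, 2, 0)

    def test_iou_rule_is_stricter(self):
        # tiny overlap passes any-overlap but fails IoU >= 0.5
        assert match_events([(0, 100)], [(99, 200)], rule="overlap")[0] == 1
        assert match_events([(0, 100)], [(99, 200)], rule="iou",
                            iou_threshold=0.5)[0] == 0

    def test_shift_invariance(self, rng):
        pred = [(10, 20), (50, 70)]
        truth = [(15, 25), (200, 210)]
        k = 1000
        shifted = match_events([(a + k, b + k) for a, b in pred],
                               [(a + k, b + k) for a, b in truth])
        assert shifted == match_events(pred, truth)


class TestScore:
    def test_arithmetic(self):
        rep = score([(10, 20), (100, 110)], [(15, 25)])
        assert rep.ppv == 50.0 and rep.sensitivity == 100.0
        assert rep.f1 == pytest.approx(2 * 0.5 * 1.0 / 1.5)

    def test_no_predictions_gives_undefined_ppv(self):
        rep = score([], [(15, 25)])
        assert rep.ppv is None and "ppv" in rep.undefined
        assert rep.sensitivity == 0.0

    def test_perfect_detection(self):
        rep = score([(10, 20)], [(10, 20)])
        assert rep.ppv == 100.0 and rep.sensitivity == 100.0 and rep.f1 == 1.0

    def test_union_monotonicity_of_sensitivity(self, rng):
        # pooling can only add coverage: the testable core of the
        # multimodal sensitivity improvement
        truth = [(100, 200), (500, 600), (900, 1000)]
        for _ in range(20):
            a = [_iv(int(s), int(s) + 50) for s in rng.integers(0, 1100, 3)]
            b = [_iv(int(s), int(s) + 50, "video") for s in rng.integers(0, 1100, 3)]
            pooled = pool_multimodal(a, b, fs=1.0, fps=1.0)
            sens = {k: score([(iv.start, iv.end) for iv in v], truth).sensitivity
                    for k, v in (("a", a), ("b", b), ("ab", pooled))}
            assert sens["ab"] >= max(sens["a"], sens["b"])


class TestAggregate:
    def test_mean_and_sem(self):
        reps = [score([(0, 10)], [(5, 15)], condition="c") for _ in range(3)]
        for r, v in zip(reps, (1.0, 2.0, 3.0)):
            r.ppv = v
        table = aggregate_reports(reps)
        assert table.loc["c", "ppv_mean"] == pytest.approx(2.0)
        assert table.loc["c", "ppv_sem"] == pytest.approx(1.0 / np.sqrt(3))
        assert table.loc["c", "ppv_n"] == 3

    def test_single_report_has_nan_sem(self):
        table = aggregate_reports([score([(0, 10)], [(5, 15)], condition="c")])
        assert table.loc["c", "ppv_n"] == 1
        assert np.isnan(table.loc["c", "ppv_sem"])

    def test_undefined_values_excluded_with_count(self):
        r1 = score([(0, 10)], [(5, 15)], condition="c")   # defined ppv
        r2 = score([], [(5, 15)], condition="c")          # undefined ppv
        table = aggregate_reports([r1, r2])
        assert table.loc["c", "ppv_n"] == 1
        assert table.loc["c", "sensitivity_n"] == 2

    def test_empty_rejected(self):
        with pytest.raises(ParameterError):
            aggregate_reports([])


class TestCrossover:
    def test_fs_mismatch_rejected(self, rng):
        from ictaldetect import fit_ar_baseline

        train = ChannelSeries(rng.standard_normal(2000), fs=256.0, patient_id="A")
        model = fit_ar_baseline(train, order=4, history_window=16)
        rec = ChannelSeries(rng.standard_normal(4000), fs=512.0, patient_id="B")
        truth = EventLabelSet(np.array([[100, 200]]), fs=512.0)
        with pytest.raises(ParameterError, match="fs"):
            crossover_run(model, rec, truth)

    def test_crossover_report_condition(self, rng):
        from ictaldetect import fit_ar_baseline
        from ictaldetect.forecast import ForecastConfig
        from ictaldetect.threshold import DynamicConfig

        fc = ForecastConfig(history_window=32)
        train = ChannelSeries(rng.standard_normal(2000), fs=256.0, patient_id="A")
        model = fit_ar_baseline(train, order=4, history_window=32)
        rec = ChannelSeries(rng.standard_normal(8000), fs=256.0, patient_id="B")
        truth = EventLabelSet(np.array([[4000, 4500]]), fs=256.0)
        report, result = crossover_run(model, rec, truth, forecast_config=fc,
                                       dynamic=DynamicConfig(window_size=1024))
        assert report.condition == "crossover"
        assert report.patient_id == "B"
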