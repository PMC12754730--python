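"""Metrics, aggregation schemes, experiment protocol, searches, agreement."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import fmdetect as fd
from fmdetect.evaluate import (ConfusionCounts, ExperimentConfig, aggregate_model1,
                               aggregate_model23, confusion, f1_score,
                               imu_threshold_search, make_classifier, mean_counts,
                               metrics, mpm_vs_udfm_agreement,
                               performance_vs_event_count, run_experiment,
                               split_train_test, stft_grid_search, valid_grid_pairs)
from fmdetect.features import WindowedDataset
from fmdetect.synthgen import AnnotationTrack, MovementEvent


class TestConfusionAndMetrics:
    def test_perfect_prediction(self):
        c = confusion([1, 0, 1, 0], [1, 0, 1, 0])
        assert (c.tp, c.tn, c.fp, c.fn) == (2, 2, 0, 0)

    def test_all_negative_prediction(self):
        c = confusion([1, 0, 1, 0], [0, 0, 0, 0])
        assert c.tp == 0 and c.fp == 0 and c.fn == 2

    def test_matches_pairwise_tally_oracle(self, rng):
        y_true = rng.integers(0, 2, 200)
        y_pred = rng.integers(0, 2, 200)
        c = confusion(y_true, y_pred)
        tally = {"tp": 0, "tn": 0, "fp": 0, "fn": 0}
        for t, p in zip(y_true, y_pred):
            tally["tp" if t and p else "tn" if not t and not p
                  else "fp" if p else "fn"] += 1
        assert (c.tp, c.tn, c.fp, c.fn) == (tally["tp"], tally["tn"],
                                            tally["fp"], tally["fn"])

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError, match="mismatch"):
            confusion([0, 1], [0])

    def test_f1_from_study_precision_recall(self):
        # harmonic mean of the concatenated model's P = 0.443, R = 0.611
        assert f1_score(0.443, 0.611) == pytest.approx(0.514, abs=5e-4)

    def test_simple_precision(self):
        rep = metrics(ConfusionCounts(tp=10, fp=10, tn=5, fn=5))
        assert rep.precision == 0.5

    def test_degenerate_recall_flagged_undefined(self):
        rep = metrics(ConfusionCounts(tp=0, fn=0, fp=3, tn=7))
        assert rep.recall is None
        assert rep.f1 is None

    def test_identity_prediction_gives_unit_metrics(self, rng):
        y = rng.integers(0, 2, 50)
        if y.sum() in (0, 50):
            y[0] = 1 - y[0]
        rep = metrics(confusion(y, y))
        assert rep.precision == rep.recall == rep.accuracy == 1.0


class TestAggregation:
    def test_identical_sensors_average_to_any_one(self):
        c = ConfusionCounts(tp=3, tn=5, fp=1, fn=2)
        rep = aggregate_model1([[c] * 6])
        assert rep.counts == c

    def test_two_scan_hand_arithmetic(self):
        a = ConfusionCounts(tp=2, fp=0, fn=2, tn=8)
        b = ConfusionCounts(tp=4, fp=2, fn=0, tn=6)
        rep = aggregate_model23([a, b])
        assert rep.counts == ConfusionCounts(tp=3, tn=7, fp=1, fn=1)
        assert rep.precision == pytest.approx(0.75)

    def test_scan_order_invariant(self):
        scans = [ConfusionCounts(1, 2, 3, 4), ConfusionCounts(5, 6, 7, 8),
                 ConfusionCounts(0, 1, 0, 1)]
        fwd = aggregate_model23(scans)
        rev = aggregate_model23(scans[::-1])
        assert fwd.counts == rev.counts

    def test_mean_commutes_with_scaling(self):
        scans = [ConfusionCounts(2, 3, 1, 4), ConfusionCounts(6, 1, 2, 3)]
        scaled = [c.scaled(7.0) for c in scans]
        assert mean_counts(scaled) == mean_counts(scans).scaled(7.0)
        # ratio metrics are scale-invariant
        assert aggregate_model23(scaled).precision == aggregate_model23(scans).precision

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            aggregate_model1([])
        with pytest.raises(ValueError):
            aggregate_model23([])


def _dataset(n=10):
    return WindowedDataset(X=np.arange(n * 2, dtype=float).reshape(n, 2),
                           y=np.arange(n) % 2,
                           window_starts_s=np.arange(n) * 6.0, scan_id="s")


class TestSplit:
    def test_seventy_thirty_chronological(self):
        train, test = split_train_test(_dataset(10), 0.7)
        assert train.n_windows == 7 and test.n_windows == 3
        assert train.window_starts_s.max() < test.window_starts_s.min()

    def test_extreme_fraction_clamped(self):
        train, test = split_train_test(_dataset(10), 0.999)
        assert train.n_windows == 9 and test.n_windows == 1

    def test_union_is_exact_partition(self):
        ds = _dataset(13)
        train, test = split_train_test(ds, 0.7)
        recombined = np.concatenate([train.window_starts_s, test.window_starts_s])
        np.testing.assert_array_equal(np.sort(recombined), ds.window_starts_s)
        assert train.n_windows + test.n_windows == ds.n_windows

    def test_too_few_windows_errors(self):
        with pytest.raises(ValueError, match="at least 2"):
            split_train_test(_dataset(1), 0.7)


@pytest.fixture(scope="module")
def three_scans():
    scans = []
    for i in range(3):
        cfg = fd.SessionConfig(duration_s=180, seed=100 + i, scan_id=f"scan{i:02d}")
        scans.append(fd.generate_recording(cfg))
    return scans


class TestRunExperiment:
    def test_end_to_end_smoke_all_metrics_defined(self, three_scans):
        res = run_experiment(three_scans, ExperimentConfig(
            model_input=2, classifier="rusboost",
            classifier_params={"n_estimators": 20}, seed=5))
        for value in res.report.as_dict().values():
            assert value is not None and 0.0 <= value <= 1.0
        assert len(res.per_scan) == 3
        assert {"scan_id", "tp", "fp", "fn", "tn", "precision", "recall"} <= set(
            res.per_scan.columns)
        assert "rusboost" in res.summary()

    def test_model_input_1_averages_six_sensors(self, three_scans):
        res = run_experiment(three_scans[:1], ExperimentConfig(
            model_input=1, classifier="tree", seed=0))
        # averaged counts still total one scan's test-window count
        counts = res.report.counts
        assert counts.total > 0
        assert counts.total == int(counts.total)  # mean of 6 equal-length sensors

    def test_identical_seeds_identical_reports(self, three_scans):
        cfg = ExperimentConfig(model_input=3, classifier="rusboost",
                               classifier_params={"n_estimators": 10}, seed=7)
        r1 = run_experiment(three_scans, cfg)
        r2 = run_experiment(three_scans, cfg)
        assert r1.report == r2.report
        pd.testing.assert_frame_equal(r1.per_scan, r2.per_scan)

    def test_no_test_events_completes_with_flag(self):
        """A scan whose test portion holds no movement still yields a report."""
        cfg = fd.SessionConfig(duration_s=180, event_rate=2, seed=11, scan_id="sparse")
        recording, track = fd.generate_recording(cfg)
        res = run_experiment([(recording, track)], ExperimentConfig(
            model_input=2, classifier="tree", seed=0))
        assert res.report.accuracy is not None  # run completed

    def test_all_classifiers_run(self, three_scans):
        for name in ("knn", "tree", "adaboost", "rusboost"):
            res = run_experiment(three_scans[:1], ExperimentConfig(
                model_input=3, classifier=name,
                classifier_params={} if name in ("knn", "tree")
                else {"n_estimators": 5}, seed=1))
            assert res.report.accuracy is not None


class TestImuThresholdSearch:
    def test_single_threshold_single_row(self, three_scans):
        table, best = imu_threshold_search(three_scans[:1], thresholds=(5.0,),
                                           config=ExperimentConfig(
                                               model_input=3, classifier="tree", seed=0))
        assert len(table) == 1 and best == 5.0

    def test_row_per_threshold(self, three_scans):
        table, _ = imu_threshold_search(three_scans[:1], thresholds=(4.0, 5.0, 6.0),
                                        config=ExperimentConfig(
                                            model_input=3, classifier="tree", seed=0))
        assert list(table["threshold"]) == [4.0, 5.0, 6.0]

    def test_constructed_fixture_selects_five(self):
        """Decoy IMU excursions at 4.5 punish threshold 4; movement-like
        artefacts at 5.5 punish threshold 6; threshold 5 gates exactly the
        artefacts and is selected."""
        from fmdetect.synthgen import make_threshold_validation_scan

        recording, track = make_threshold_validation_scan(seed=15, artefact_seed=31)
        table, best = imu_threshold_search(
            [(recording, track)], (4.0, 5.0, 6.0),
            ExperimentConfig(model_input=2, classifier="rusboost",
                             classifier_params={"n_estimators": 30}, seed=2))
        assert best == 5.0
        assert len(table) == 3


class TestStftGridSearch:
    def test_restricted_grid_returns_only_pair(self, three_scans):
        best, table = stft_grid_search(three_scans[:1], windows=[8], overlaps=[2],
                                       config=ExperimentConfig(
                                           model_input=3, classifier="tree", seed=0))
        assert best == (8.0, 2.0) and len(table) == 1

    def test_valid_pair_count_by_enumeration(self):
        pairs = valid_grid_pairs(range(2, 11), range(1, 5))
        oracle = sum(1 for w in range(2, 11) for o in range(1, 5) if o < w)
        assert len(pairs) == oracle == 30
        assert (2, 2) not in pairs and (2, 1) in pairs

    def test_invalid_only_grid_errors(self):
        with pytest.raises(ValueError, match="valid"):
            stft_grid_search([], windows=[2], overlaps=[3, 4])

    def test_two_pair_search_deterministic(self, three_scans):
        cfg = ExperimentConfig(model_input=3, classifier="tree", seed=3)
        best1, t1 = stft_grid_search(three_scans[:1], [6, 8], [2], cfg)
        best2, t2 = stft_grid_search(three_scans[:1], [6, 8], [2], cfg)
        assert best1 == best2
        pd.testing.assert_frame_equal(t1, t2)


class TestPerformanceVsEventCount:
    def test_equal_counts_undefined_correlation(self):
        per_scan = pd.DataFrame({"scan_id": ["a", "b"], "n_udfm": [5, 5],
                                 "precision": [0.5, 0.6], "recall": [0.4, 0.7]})
        table, corr = performance_vs_event_count(per_scan)
        assert corr["recall"] is None and corr["precision"] is None
        assert len(table) == 2

    def test_table_sorted_by_count(self):
        per_scan = pd.DataFrame({"scan_id": list("abc"), "n_udfm": [50, 5, 200],
                                 "precision": [0.5, 0.2, 0.9],
                                 "recall": [0.5, 0.1, 0.9]})
        table, corr = performance_vs_event_count(per_scan)
        assert list(table["n_udfm"]) == [5, 50, 200]
        assert corr["recall"] == pytest.approx(1.0)

    def test_recall_rises_with_event_count(self):
        """More movement events -> better detection (pooled over 3 scans per
        count level; single sparse scans give recall on 1-2 windows only)."""
        passes = 0
        for seed in range(10):
            recalls = []
            for count in (5, 50, 200):
                scans = [
                    fd.generate_recording(fd.SessionConfig(
                        duration_s=900, event_rate=count, seed=7000 + seed * 100 + count + r,
                        scan_id=f"c{count}r{r}"))
                    for r in range(3)
                ]
                res = run_experiment(scans, ExperimentConfig(
                    model_input=2, classifier="rusboost",
                    classifier_params={"n_estimators": 30}, seed=seed))
                recalls.append(res.report.recall)
            passes += all(a is None or b is None or a <= b + 1e-12
                          for a, b in zip(recalls, recalls[1:]))
        assert passes >= 8


class TestStructuralProperties:
    def test_recall_ceiling_on_strongly_separable_sessions(self):
        """Large-amplitude single-class events with no probe noise push the
        concatenated-input RUSBoost recall to >= 0.9 (sanity ceiling).

        Rectangular frames are used here: with any-overlap labels, a Hann
        taper hides events clipped at frame edges, capping recall ~0.87
        regardless of amplitude."""
        mix = {"general": 1.0, "limb": 0.0, "breathing": 0.0, "startle": 0.0}
        scans = [
            fd.generate_recording(fd.SessionConfig(
                duration_s=900, event_amplitude=15.0, probe_episode_rate=0,
                event_class_mix=mix, seed=i, scan_id=f"s{i}"))
            for i in range(4)
        ]
        res = run_experiment(scans, ExperimentConfig(
            model_input=2, classifier="rusboost",
            classifier_params={"n_estimators": 100}, seed=0,
            spectral_cfg=fd.SpectralConfig(taper=None)))
        assert res.report.recall >= 0.9

    def test_f1_similar_across_model_inputs(self):
        """The three fusion strategies score within 0.15 F1 of each other
        on default-density sessions (loose structural property, 5 seeds)."""
        for seed in range(5):
            scans = [
                fd.generate_recording(fd.SessionConfig(
                    duration_s=420, seed=1000 * seed + i, scan_id=f"s{i}"))
                for i in range(2)
            ]
            f1s = []
            for model_input in (1, 2, 3):
                res = run_experiment(scans, ExperimentConfig(
                    model_input=model_input, classifier="rusboost",
                    classifier_params={"n_estimators": 30}, seed=seed))
                f1s.append(res.report.f1)
            assert all(f1 is not None for f1 in f1s)
            assert max(f1s) - min(f1s) <= 0.15


class TestAgreement:
    def _track(self, events, presses):
        return AnnotationTrack(events=events, mpm_press_s=presses, scan_id="t")

    def test_all_perceived_no_spurious_all_ones(self):
        events = [MovementEvent(10.0, 1.0, "general", True),
                  MovementEvent(40.0, 1.0, "limb", True)]
        rep = mpm_vs_udfm_agreement(self._track(events, [10.5, 40.4]),
                                    window_s=8.0, duration_s=64.0)
        assert (rep.precision, rep.recall, rep.specificity, rep.accuracy) == (1, 1, 1, 1)

    def test_no_presses_zero_precision_full_specificity(self):
        events = [MovementEvent(10.0, 1.0, "general", False)]
        rep = mpm_vs_udfm_agreement(self._track(events, []), 8.0, duration_s=64.0)
        assert rep.precision == 0.0 and rep.specificity == 1.0

    def test_spurious_press_counts_against_recall_and_specificity(self):
        events = [MovementEvent(10.0, 1.0, "general", True)]
        rep = mpm_vs_udfm_agreement(self._track(events, [10.5, 50.0]), 8.0,
                                    duration_s=64.0)
        assert rep.precision == 1.0
        assert rep.recall == pytest.approx(0.5)
        assert rep.specificity == pytest.approx(6 / 7)

    def test_empty_session_errors(self):
        with pytest.raises(ValueError, match="empty session"):
            mpm_vs_udfm_agreement(self._track([], []))

    def test_precision_recovers_perception_probability(self):
        """Pooled over 50 sparse sessions, the perceived fraction of
        UDFM-positive windows estimates perception_prob = 0.61."""
        tp = fn = 0.0
        for seed in range(50):
            cfg = fd.SessionConfig(duration_s=600, event_rate=12,
                                   probe_episode_rate=0, seed=seed)
            _, track = fd.generate_recording(cfg)
            rep = mpm_vs_udfm_agreement(track, 8.0, duration_s=600.0)
            tp += rep.counts.tp
            fn += rep.counts.fn
        p = tp / (tp + fn)
        se = np.sqrt(0.61 * 0.39 / (tp + fn))
        assert abs(p - 0.61) < 3 * se
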