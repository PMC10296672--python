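"""Threshold calibration, run extraction/bridging, and end-to-end detection."""

import numpy as np
import pytest

from mwcolon import array_forward as af
from mwcolon import detection as det
from mwcolon import quality as q
from mwcolon import scene as sc
from mwcolon.imaging import ContrastMap


def make_map(aggregate):
    """A contrast map whose profile carries the aggregate in bin 0."""
    aggregate = np.asarray(aggregate, dtype=float)
    profiles = np.zeros((len(aggregate), 64))
    profiles[:, 0] = aggregate
    return ContrastMap(profiles=profiles, aggregate=profiles.max(axis=1))


def all_valid(n):
    return q.ValidityMask(flags=np.array([q.VALID] * n, dtype=object),
                          scores=np.zeros(n, int))


CFG = det.DetectorConfig(calib_frames=5)


class TestCalibrateThreshold:
    def test_zero_map_gives_zero_threshold(self):
        map_ = make_map(np.zeros(20))
        assert det.calibrate_threshold(map_, all_valid(20), CFG) == 0.0

    def test_constant_aggregate_gives_that_constant(self):
        map_ = make_map(np.full(20, 3.7))
        assert det.calibrate_threshold(map_, all_valid(20), CFG) == pytest.approx(3.7)

    def test_threshold_increases_with_k_sigma(self):
        rng = np.random.default_rng(0)
        map_ = make_map(rng.random(20))
        thetas = [
            det.calibrate_threshold(
                map_, all_valid(20), det.DetectorConfig(k_sigma=k, calib_frames=5)
            )
            for k in (1.0, 3.0, 5.0)
        ]
        assert thetas[0] < thetas[1] < thetas[2]

    def test_too_few_valid_frames_rejected(self):
        map_ = make_map(np.zeros(3))
        with pytest.raises(ValueError):
            det.calibrate_threshold(map_, all_valid(3), CFG)

    def test_invalid_frames_skipped_in_calibration(self):
        agg = np.zeros(20)
        agg[:3] = 100.0  # corrupted but invalid -> must be ignored
        flags = np.array([q.INVALID_CONTACT] * 3 + [q.VALID] * 17, dtype=object)
        mask = q.ValidityMask(flags=flags, scores=np.zeros(20, int))
        assert det.calibrate_threshold(make_map(agg), mask, CFG) == 0.0


class TestFindRuns:
    def test_nothing_above_threshold(self):
        runs = det.find_runs(make_map(np.zeros(50)), all_valid(50), 1.0, CFG)
        assert runs == []

    def test_single_run_extracted(self):
        agg = np.zeros(200)
        agg[100:131] = 5.0
        runs = det.find_runs(make_map(agg), all_valid(200), 1.0, CFG)
        assert runs == [(100, 131)]

    def test_gap_bridging_matches_frame_enumeration_oracle(self):
        agg = np.zeros(200)
        agg[100:111] = 5.0
        agg[113:121] = 5.0  # gap of 2 <= gap_bridge=3 -> merged
        runs = det.find_runs(make_map(agg), all_valid(200), 1.0, CFG)
        assert runs == [(100, 121)]

    def test_gap_wider_than_bridge_splits_runs(self):
        agg = np.zeros(200)
        agg[100:111] = 5.0
        agg[115:121] = 5.0  # gap of 4 > gap_bridge=3
        runs = det.find_runs(make_map(agg), all_valid(200), 1.0, CFG)
        assert runs == [(100, 111), (115, 121)]

    def test_invalid_frames_never_start_or_end_a_run(self):
        agg = np.full(30, 5.0)
        flags = np.array([q.VALID] * 30, dtype=object)
        flags[:10] = q.INVALID_CONTACT
        flags[25:] = q.INVALID_CONTACT
        mask = q.ValidityMask(flags=flags, scores=np.zeros(30, int))
        runs = det.find_runs(make_map(agg), mask, 1.0, CFG)
        assert runs == [(10, 25)]

    def test_runs_disjoint_and_sorted(self):
        rng = np.random.default_rng(3)
        agg = (rng.random(500) > 0.7) * 5.0
        runs = det.find_runs(make_map(agg), all_valid(500), 1.0, CFG)
        for (s1, e1), (s2, e2) in zip(runs, runs[1:]):
            assert e1 < s2


class TestClassifyRuns:
    def test_width_criterion(self):
        map_ = make_map(np.full(100, 5.0))
        events = det.classify_runs([(0, 20), (30, 33), (40, 50)], map_, CFG)
        assert [e.label for e in events] == ["polyp", "stool", "polyp"]
        # length exactly L_min (10) is inclusive -> polyp
        assert events[2].length == CFG.L_min

    def test_theta_peak_located(self):
        profiles = np.zeros((50, 64))
        profiles[20:40, 17] = 9.0
        map_ = ContrastMap(profiles=profiles, aggregate=profiles.max(axis=1))
        (event,) = det.classify_runs([(20, 40)], map_, CFG)
        assert event.peak_contrast == 9.0
        bin_width = 2 * np.pi / 64
        assert event.theta_peak == pytest.approx((17 + 0.5) * bin_width)


class TestDetectEndToEnd:
    def test_healthy_stream_produces_no_events(self):
        stream, _ = af.simulate_stream(sc.SceneTimeline(n_frames=100), noise_sigma=1e-3)
        events, _, mask = det.detect(stream)
        assert events == []
        assert mask.valid.all()

    def test_isolated_polyp_yields_one_overlapping_polyp_event(self):
        polyp = sc.Inclusion(kind="polyp", theta_center=2.0, theta_width=0.3,
                             frame_start=80, frame_extent=20)
        stream, truth = af.simulate_stream(
            sc.SceneTimeline(n_frames=150, inclusions=(polyp,)), noise_sigma=1e-3
        )
        events, _, _ = det.detect(stream)
        polyp_events = [e for e in events if e.label == "polyp"]
        assert len(polyp_events) == 1
        ev = polyp_events[0]
        assert max(ev.frame_start, 80) < min(ev.frame_end, 100)

    def test_stool_yields_stool_event_not_polyp(self):
        stool = sc.Inclusion(kind="stool", theta_center=2.0, theta_width=0.3,
                             frame_start=80, frame_extent=3)
        stream, _ = af.simulate_stream(
            sc.SceneTimeline(n_frames=150, inclusions=(stool,)), noise_sigma=1e-3
        )
        events, _, _ = det.detect(stream)
        assert [e.label for e in events] == ["stool"]

    @pytest.mark.parametrize("seed", range(20))
    def test_isolated_polyps_detected_across_seeds(self, seed):
        rng = np.random.default_rng(seed)
        extent = int(rng.integers(15, 41))
        start = int(rng.integers(60, 150 - extent))
        polyp = sc.Inclusion(
            kind="polyp", theta_center=float(rng.uniform(0, 2 * np.pi)),
            theta_width=0.3, frame_start=start, frame_extent=extent,
        )
        stream, truth = af.simulate_stream(
            sc.SceneTimeline(n_frames=150, inclusions=(polyp,)),
            noise_sigma=1e-3, seed=seed,
        )
        events, _, _ = det.detect(stream)
        polyp_events = [e for e in events if e.label == "polyp"]
        assert len(polyp_events) == 1
        ev = polyp_events[0]
        assert max(ev.frame_start, start) < min(ev.frame_end, start + extent)

    def test_events_reproducible_from_same_stream(self):
        stream, _ = af.simulate_stream(sc.replica_fig3_timeline(3), seed=3)
        e1, m1, _ = det.detect(stream)
        e2, m2, _ = det.detect(stream)
        assert e1 == e2
        np.testing.assert_array_equal(m1.profiles, m2.profiles)
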