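"""Baseline estimation, matched-filter reconstruction, and the contrast map."""

import math

import numpy as np
import pytest

from mwcolon import array_forward as af
from mwcolon import imaging as im
from mwcolon import scene as sc

from conftest import make_scatterer


class TestEstimateBaseline:
    def test_noise_free_healthy_stream_recovers_exact_baseline(self):
        stream, _ = af.simulate_stream(sc.SceneTimeline(n_frames=30), noise_sigma=0.0)
        est = im.estimate_baseline(stream, window=10)
        np.testing.assert_array_equal(est, stream.baseline.data)

    def test_estimate_ignores_frames_after_window(self):
        polyp = sc.Inclusion(kind="polyp", theta_center=1.0, theta_width=0.3,
                             frame_start=20, frame_extent=10)
        tl = sc.SceneTimeline(n_frames=30, inclusions=(polyp,))
        stream, _ = af.simulate_stream(tl, noise_sigma=0.0)
        est = im.estimate_baseline(stream, window=20)
        np.testing.assert_array_equal(est, stream.baseline.data)

    def test_error_shrinks_with_window(self):
        # Monte-Carlo: median over 50 noisy frames beats median over 5
        tl = sc.SceneTimeline(n_frames=60)
        devs = {}
        for window in (5, 50):
            errs = []
            for seed in range(10):
                stream, _ = af.simulate_stream(tl, noise_sigma=1e-3, seed=seed)
                est = im.estimate_baseline(stream, window=window)
                errs.append(np.abs(est - stream.baseline.data).max())
            devs[window] = np.mean(errs)
        assert devs[50] < devs[5]

    def test_window_longer_than_stream_rejected(self):
        stream, _ = af.simulate_stream(sc.SceneTimeline(n_frames=10), noise_sigma=0.0)
        with pytest.raises(ValueError):
            im.estimate_baseline(stream, window=11)


class TestReconstructFrame:
    def test_baseline_frame_reconstructs_to_zero(self, geometry, schedule, k_bg,
                                                 baseline, grid, reconstructor):
        frame = af.simulate_frame(geometry, schedule, [], k_bg, baseline)
        img = reconstructor.reconstruct(frame, baseline)
        assert img.pixels.max() == 0.0

    def test_single_scatterer_localized_within_one_cell(
        self, geometry, schedule, k_bg, baseline, grid, reconstructor
    ):
        rng = np.random.default_rng(42)
        for _ in range(25):
            theta = rng.uniform(0, 2 * math.pi)
            r = 13.0
            s = make_scatterer(r=r, theta=theta)
            frame = af.simulate_frame(geometry, schedule, [s], k_bg, baseline)
            img = reconstructor.reconstruct(frame, baseline)
            ir, it = np.unravel_index(np.argmax(img.pixels), img.pixels.shape)
            true_theta_bin = grid.theta_bin(theta)
            dtheta = min((it - true_theta_bin) % grid.n_theta,
                         (true_theta_bin - it) % grid.n_theta)
            true_r_bin = int(r / grid.r_max * grid.n_r)
            assert dtheta <= 1
            assert abs(ir - true_r_bin) <= 1

    def test_image_linear_in_contrast(self, geometry, schedule, k_bg, baseline,
                                      reconstructor):
        s1 = make_scatterer(chi=0.1 + 0.02j)
        s2 = make_scatterer(chi=0.2 + 0.04j)
        f1 = af.simulate_frame(geometry, schedule, [s1], k_bg, baseline)
        f2 = af.simulate_frame(geometry, schedule, [s2], k_bg, baseline)
        i1 = reconstructor.reconstruct(f1, baseline)
        i2 = reconstructor.reconstruct(f2, baseline)
        np.testing.assert_allclose(i2.pixels, 2.0 * i1.pixels, rtol=1e-8)

    def test_baseline_length_mismatch_rejected(self, baseline, reconstructor,
                                               geometry, schedule, k_bg):
        frame = af.simulate_frame(geometry, schedule, [], k_bg, baseline)
        with pytest.raises(ValueError):
            reconstructor.reconstruct(frame, baseline[:10])


class TestAggregateFrame:
    def test_zero_image(self, grid):
        img = im.FrameImage(0, grid, np.zeros((grid.n_r, grid.n_theta)))
        profile, agg = im.aggregate_frame(img)
        assert profile.sum() == 0.0 and agg == 0.0

    def test_single_hot_pixel(self, grid):
        px = np.zeros((grid.n_r, grid.n_theta))
        px[7, 33] = 4.2
        profile, agg = im.aggregate_frame(im.FrameImage(0, grid, px))
        assert agg == 4.2
        assert profile[33] == 4.2
        assert np.count_nonzero(profile) == 1

    def test_invariant_under_radial_permutation(self, grid):
        rng = np.random.default_rng(0)
        px = rng.random((grid.n_r, grid.n_theta))
        shuffled = px[rng.permutation(grid.n_r), :]
        _, agg1 = im.aggregate_frame(im.FrameImage(0, grid, px))
        _, agg2 = im.aggregate_frame(im.FrameImage(0, grid, shuffled))
        assert agg1 == agg2


class TestContrastMap:
    def test_healthy_noise_free_stream_maps_to_zero(self, grid):
        stream, _ = af.simulate_stream(sc.SceneTimeline(n_frames=20), noise_sigma=0.0)
        map_ = im.build_contrast_map(stream, stream.baseline.data, grid)
        assert map_.profiles.max() == 0.0

    def test_replica_stream_has_600_rows(self, grid):
        stream, _ = af.simulate_stream(sc.replica_fig3_timeline(0), seed=0)
        baseline = im.estimate_baseline(stream)
        map_ = im.build_contrast_map(stream, baseline, grid)
        assert map_.profiles.shape == (600, grid.n_theta)
        assert map_.n_frames == 600

    def test_rows_consistent_with_per_frame_reconstruction(
        self, geometry, schedule, grid, reconstructor
    ):
        polyp = sc.Inclusion(kind="polyp", theta_center=2.0, theta_width=0.3,
                             frame_start=5, frame_extent=10)
        stream, _ = af.simulate_stream(
            sc.SceneTimeline(n_frames=20, inclusions=(polyp,)), noise_sigma=0.0
        )
        base = stream.baseline.data
        map_ = im.build_contrast_map(stream, base, grid)
        for f in (0, 7, 12, 19):
            profile, agg = im.aggregate_frame(
                reconstructor.reconstruct(stream.frames[f], base)
            )
            np.testing.assert_array_equal(map_.profiles[f], profile)
            assert map_.aggregate[f] == agg

    def test_rotating_scene_shifts_profile_by_eighth_turn(self, grid):
        def profile_for(theta):
            polyp = sc.Inclusion(kind="polyp", theta_center=theta, theta_width=0.3,
                                 frame_start=0, frame_extent=1)
            stream, _ = af.simulate_stream(
                sc.SceneTimeline(n_frames=1, inclusions=(polyp,)), noise_sigma=0.0
            )
            map_ = im.build_contrast_map(stream, stream.baseline.data, grid)
            return map_.profiles[0]

        p0 = profile_for(0.7)
        p45 = profile_for(0.7 + 2 * math.pi / 8)
        np.testing.assert_allclose(p45, np.roll(p0, grid.n_theta // 8), rtol=1e-9)

    def test_aggregate_monotone_in_contrast(self, geometry, schedule, k_bg,
                                            baseline, grid, reconstructor):
        aggs = []
        for scale in (0.5, 1.0, 2.0):
            s = make_scatterer(chi=scale * (0.2 + 0.05j))
            frame = af.simulate_frame(geometry, schedule, [s], k_bg, baseline)
            _, agg = im.aggregate_frame(reconstructor.reconstruct(frame, baseline))
            aggs.append(agg)
        assert aggs[0] < aggs[1] < aggs[2]
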