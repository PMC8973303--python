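"""Spot detection, linking (with brute-force oracle), and track metrics."""

import numpy as np
import pytest

from mitomotility import (DetectionParams, SimParams, SpotDetection, Track,
                          classify_motility, detect_spots, integrated_distance,
                          link_tracks, net_displacement, simulate_field_movie,
                          summarize_field)
from mitomotility.tracking import detect_movie, track_movie

from conftest import render_gaussian_frame
from oracles import link_bruteforce


class TestDetection:
    def test_single_spot_subpixel(self, det_params):
        rng = np.random.default_rng(0)
        frame = render_gaussian_frame((64, 64), [(20.0, 30.0)], noise_rng=rng)
        dets = detect_spots(frame, det_params)
        assert len(dets) == 1
        assert abs(dets[0].x - 20.0) < 0.5
        assert abs(dets[0].y - 30.0) < 0.5

    def test_background_only_frame(self, det_params):
        rng = np.random.default_rng(1)
        frame = rng.poisson(10.0, size=(64, 64)).astype(float)
        assert detect_spots(frame, det_params) == []

    def test_constant_frame(self, det_params):
        assert detect_spots(np.full((32, 32), 7.0), det_params) == []

    def test_two_resolved_spots(self, det_params):
        rng = np.random.default_rng(2)
        sigma = 1.5
        frame = render_gaussian_frame(
            (64, 64), [(20.0, 32.0), (20.0 + 10 * sigma, 32.0)], sigma=sigma,
            noise_rng=rng)
        assert len(detect_spots(frame, det_params)) == 2

    def test_rejects_invalid_frame(self, det_params):
        with pytest.raises(ValueError):
            detect_spots(np.array([[1.0, np.nan], [0.0, 0.0]]), det_params)


class TestTrackGeometry:
    def test_integrated_distance_hand_sum(self):
        tr = Track(0, [0, 1, 2, 3], [0, 1, 2, 1], [0, 0, 0, 0])
        assert integrated_distance(tr, 1.0) == pytest.approx(3.0)
        assert net_displacement(tr, 1.0) == pytest.approx(1.0)

    def test_single_point_track(self):
        tr = Track(0, [5], [3.0], [4.0])
        assert integrated_distance(tr, 1.0) == 0.0
        assert net_displacement(tr, 1.0) == 0.0

    def test_triangle_inequality_random_tracks(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            n = rng.integers(2, 30)
            tr = Track(0, np.arange(n), rng.normal(0, 5, n), rng.normal(0, 5, n))
            assert (integrated_distance(tr, 0.3)
                    >= net_displacement(tr, 0.3) - 1e-12)

    def test_frames_must_increase(self):
        with pytest.raises(ValueError):
            Track(0, [0, 0, 1], [0, 1, 2], [0, 0, 0])


class TestLinking:
    def test_three_separated_particles_match_truth(self, det_params):
        p = SimParams.field_regime(n_axons=3, particles_per_axon=1,
                                   fraction_motile=1.0, seed=11, n_frames=15)
        movie, gt = simulate_field_movie(p)
        tracks = track_movie(movie, det_params)
        full = [t for t in tracks if len(t) >= 14]
        assert len(full) == 3
        for tr in full:
            # match to the nearest ground-truth particle at each frame
            errs = []
            for pid, grp in gt.positions.groupby("particle"):
                grp = grp.set_index("frame")
                common = [f for f in tr.frames if f in grp.index]
                dx = tr.xs[np.isin(tr.frames, common)] - grp.loc[common, "x_px"]
                dy = tr.ys[np.isin(tr.frames, common)] - grp.loc[common, "y_px"]
                errs.append(np.hypot(dx, dy).max())
            assert min(errs) < 0.5

    def test_single_detection_single_point_track(self, det_params):
        dets = [[SpotDetection(0, 10.0, 10.0, 5.0)], []]
        tracks = link_tracks(dets, det_params, pixel_size=0.3)
        assert len(tracks) == 1
        assert len(tracks[0]) == 1

    def test_needs_two_frames(self, det_params):
        with pytest.raises(ValueError):
            link_tracks([[SpotDetection(0, 1.0, 1.0, 1.0)]], det_params, 0.3)

    @pytest.mark.parametrize("seed", range(6))
    def test_bruteforce_oracle_equivalence(self, seed):
        """Linking equals exhaustive-assignment linking on small movies."""
        rng = np.random.default_rng(seed)
        params = DetectionParams(link_gate_um=1.0, gap_close_frames=0)
        pixel_size = 0.3
        gate_px = params.link_gate_um / pixel_size
        n_particles = int(rng.integers(2, 5))
        n_frames = 6
        pos = rng.uniform(5, 45, size=(n_particles, 2))
        per_frame = []
        for t in range(n_frames):
            pos = pos + rng.normal(0, 0.8, size=pos.shape)
            keep = rng.random(n_particles) > 0.15   # occasional dropouts
            per_frame.append(pos[keep].copy())
        dets = [[SpotDetection(t, x, y, 1.0) for x, y in frame]
                for t, frame in enumerate(per_frame)]
        tracks = link_tracks(dets, params, pixel_size)
        got = {tuple((int(f), x, y) for f, x, y
                     in zip(tr.frames, tr.xs, tr.ys)) for tr in tracks}
        expected = link_bruteforce(per_frame, gate_px)
        assert got == expected

    def test_permutation_invariance(self, det_params):
        rng = np.random.default_rng(9)
        frames = []
        for t in range(5):
            pts = rng.uniform(5, 45, size=(4, 2))
            frames.append([SpotDetection(t, x, y, 1.0) for x, y in pts])
        tracks_a = link_tracks(frames, det_params, 0.3)
        shuffled = [list(reversed(f)) for f in frames]
        tracks_b = link_tracks(shuffled, det_params, 0.3)
        key = lambda trs: sorted(
            tuple(zip(tr.frames.tolist(), tr.xs.tolist(), tr.ys.tolist()))
            for tr in trs)
        assert key(tracks_a) == key(tracks_b)


class TestClassification:
    def test_directed_run_is_motile(self, det_params):
        # 0.2 um/s for 30 s at 0.3 um/px: 6 um >= 2 um threshold
        x = np.linspace(0, 6 / 0.3, 31)
        tr = Track(0, np.arange(31), x, np.zeros(31))
        assert classify_motility(tr, det_params, 0.3) is True

    def test_jitter_is_stationary(self, det_params):
        rng = np.random.default_rng(5)
        anchor = np.array([20.0, 20.0])
        pts = anchor + rng.normal(0, 0.3, size=(31, 2))
        tr = Track(0, np.arange(31), pts[:, 0], pts[:, 1])
        assert classify_motility(tr, det_params, 0.3) is False

    def test_accuracy_outside_gray_zone(self, det_params):
        """>=95% correct for velocities away from the threshold boundary."""
        rng = np.random.default_rng(6)
        n_frames, dt, px = 31, 1.0, 0.3
        correct = total = 0
        for v, should_be_motile in [(0.02, False), (0.04, False),
                                    (0.1, True), (0.15, True), (0.25, True)]:
            for _ in range(40):
                x_um = v * dt * np.arange(n_frames)
                noise = rng.normal(0, 0.045, size=(n_frames, 2))
                tr = Track(0, np.arange(n_frames),
                           x_um / px + noise[:, 0] / px, noise[:, 1] / px)
                got = classify_motility(tr, det_params, px)
                correct += (got == should_be_motile)
                total += 1
        assert correct / total >= 0.95


class TestFieldSummary:
    def _track(self, pid, dist_um, motile, px=1.0, n=31):
        # straight run of total length dist_um; stationary tracks sit still
        x = np.linspace(0, dist_um / px, n) if motile else np.zeros(n)
        tr = Track(pid, np.arange(n), x, np.zeros(n))
        tr.motile = motile
        return tr

    def test_arithmetic(self, det_params):
        tracks = ([self._track(i, d, True) for i, d in enumerate([4., 5., 6.])]
                  + [self._track(3 + i, 0.0, False) for i in range(7)])
        fs = summarize_field(tracks, det_params, 1.0, distance_smooth_window=1)
        assert fs.mean_integrated_distance_um == pytest.approx(5.0)
        assert fs.percent_motile == pytest.approx(30.0)
        assert fs.n_tracks == 10

    def test_all_stationary(self, det_params):
        tracks = [self._track(i, 0.0, False) for i in range(5)]
        fs = summarize_field(tracks, det_params, 1.0)
        assert fs.percent_motile == 0.0
        assert fs.n_motile == 0
        assert fs.mean_integrated_distance_um == 0.0

    def test_mean_over_all_option(self, det_params):
        tracks = ([self._track(0, 4.0, True)]
                  + [self._track(1, 0.0, False)])
        fs = summarize_field(tracks, det_params, 1.0, mean_over="all",
                             distance_smooth_window=1)
        assert fs.mean_integrated_distance_um == pytest.approx(2.0)

    def test_requires_tracks(self, det_params):
        with pytest.raises(ValueError):
            summarize_field([], det_params, 1.0)

    def test_percent_motile_ordering(self, det_params):
        """Estimated percent motile orders with simulated motile fraction."""
        est = {}
        for fm in (0.10, 0.20):
            vals = []
            for seed in (21, 22, 23):
                p = SimParams.field_regime(fraction_motile=fm, seed=seed)
                movie, _ = simulate_field_movie(p)
                tracks = track_movie(movie, det_params)
                fs = summarize_field(tracks, det_params, movie.pixel_size,
                                     n_frames=movie.n_frames)
                vals.append(fs.percent_motile)
            est[fm] = np.mean(vals)
        assert est[0.10] < est[0.20]
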