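"""Kymograph construction, trace extraction, and axon-level metrics."""

import numpy as np
import pytest

from mitomotility import (AxonPath, DetectionParams, Movie, SimParams,
                          axon_density, build_kymograph, extract_traces,
                          simulate_axon_movie, trace_metrics)
from mitomotility.kymograph import Trace, _classify_trace


def straight_path(length_px=100, y=16.0, soma_at_start=True):
    return AxonPath(np.array([[2.0, y], [2.0 + length_px, y]]),
                    soma_at_start=soma_at_start)


class TestBuildKymograph:
    def test_stationary_particle_vertical_ridge(self, det_params):
        p = SimParams(field_size=(32, 128), n_frames=40, fraction_motile=0.0,
                      particles_per_axon=1, jitter_px=0.05, seed=1)
        movie, gt = simulate_axon_movie(p)
        k = build_kymograph(movie, gt.paths[0])
        assert k.data.shape[0] == movie.n_frames
        cols = k.data.argmax(axis=1)
        assert np.ptp(cols) <= 2

    def test_moving_ridge_slope(self, det_params):
        p = SimParams(field_size=(32, 256), n_frames=120, fraction_motile=1.0,
                      p_pause=0.0, v_antero_mean=0.2, v_retro_mean=0.2,
                      v_sd=0.0, p_anterograde=1.0, particles_per_axon=1, seed=2)
        movie, gt = simulate_axon_movie(p)
        k = build_kymograph(movie, gt.paths[0])
        t = np.arange(k.n_frames) * k.time_scale_s
        ridge_um = k.data.argmax(axis=1) * k.pos_scale_um
        slope = np.polyfit(t, ridge_um, 1)[0]
        assert slope == pytest.approx(0.2, rel=0.05)

    def test_empty_region_is_background(self):
        movie = Movie(np.full((10, 32, 128), 20.0), 0.2, 0.5)
        k = build_kymograph(movie, straight_path())
        assert np.allclose(k.data, 20.0)

    def test_path_outside_frame_names_vertex(self):
        movie = Movie(np.zeros((3, 32, 64)), 0.2, 0.5)
        bad = AxonPath(np.array([[2.0, 10.0], [100.0, 10.0]]))
        with pytest.raises(ValueError, match="vertex 1"):
            build_kymograph(movie, bad)

    def test_band_width_validation(self):
        movie = Movie(np.zeros((3, 32, 64)), 0.2, 0.5)
        with pytest.raises(ValueError):
            build_kymograph(movie, straight_path(length_px=50), band_width=0)


class TestExtractTraces:
    def test_recovers_all_particles(self, det_params):
        p = SimParams(field_size=(48, 256), n_frames=60, fraction_motile=0.0,
                      particles_per_axon=5, seed=4)
        movie, gt = simulate_axon_movie(p)
        traces = extract_traces(movie, gt.paths[0], det_params)
        full = [t for t in traces if len(t.frames) >= 50]
        assert len(full) == 5
        # projected coordinates match ground-truth s within 0.5 um
        for tr in full:
            s_mine = np.median(tr.s_um)
            errs = []
            for pid, grp in gt.positions.groupby("particle"):
                errs.append(abs(np.median(grp["s_um"]) - s_mine))
            assert min(errs) < 0.5

    def test_empty_axon(self, det_params):
        rng = np.random.default_rng(5)
        frames = rng.poisson(20.0, size=(10, 32, 128)).astype(float)
        movie = Movie(frames, 0.2, 0.5)
        assert extract_traces(movie, straight_path(), det_params) == []

    def test_retrograde_sign_convention(self, det_params):
        p = SimParams(field_size=(32, 256), n_frames=120, fraction_motile=1.0,
                      p_pause=0.0, v_antero_mean=0.2, v_retro_mean=0.2,
                      v_sd=0.0, p_anterograde=0.0, particles_per_axon=1, seed=6)
        movie, gt = simulate_axon_movie(p)
        traces = extract_traces(movie, gt.paths[0], det_params)
        main = max(traces, key=lambda t: len(t.frames))
        assert main.net_ds_um < 0
        assert main.direction == "retrograde"


class TestTraceMetrics:
    def _trace(self, pid, net_um, n=60, dt=0.5):
        s = np.linspace(10.0, 10.0 + net_um, n)
        tr = Trace(pid, np.arange(n), s)
        _classify_trace(tr, 2.0)
        return tr

    def test_direction_percentages(self):
        traces = ([self._trace(0, 5.0), self._trace(1, 4.0)]        # antero
                  + [self._trace(2, -5.0)]                          # retro
                  + [self._trace(3 + i, 0.0) for i in range(7)])    # still
        m = trace_metrics(traces, frame_interval=0.5)
        assert m.percent_anterograde == pytest.approx(20.0)
        assert m.percent_retrograde == pytest.approx(10.0)
        assert m.percent_motile == pytest.approx(30.0)
        assert (m.percent_anterograde + m.percent_retrograde
                == pytest.approx(m.percent_motile))

    def test_all_stationary(self):
        traces = [self._trace(i, 0.0) for i in range(4)]
        m = trace_metrics(traces, frame_interval=0.5)
        assert m.percent_motile == 0.0
        assert m.velocity_anterograde_um_s is None
        assert m.velocity_retrograde_um_s is None

    def test_constant_velocity_recovery(self):
        # noiseless constant-velocity trace: run speed equals the slope
        n, dt, v = 120, 0.5, 0.21
        s = 5.0 + v * dt * np.arange(n)
        tr = Trace(0, np.arange(n), s)
        _classify_trace(tr, 2.0)
        m = trace_metrics([tr], frame_interval=dt)
        # smoothing flattens the first/last half-window; ~1% end effect
        assert m.velocity_anterograde_um_s == pytest.approx(v, rel=0.02)

    def test_velocity_recovery_from_movies(self, det_params):
        """Simulated run speeds recovered within 10% from rendered movies."""
        for v in (0.10, 0.21):
            rec = []
            for seed in (31, 32):
                p = SimParams(fraction_motile=1.0, p_pause=0.0,
                              v_antero_mean=v, v_retro_mean=v, v_sd=0.0,
                              particles_per_axon=5, seed=seed)
                movie, gt = simulate_axon_movie(p)
                m = trace_metrics(extract_traces(movie, gt.paths[0], det_params),
                                  movie.frame_interval)
                for val in (m.velocity_anterograde_um_s,
                            m.velocity_retrograde_um_s):
                    if val is not None:
                        rec.append(val)
            assert np.mean(rec) == pytest.approx(v, rel=0.10)

    def test_needs_traces(self):
        with pytest.raises(ValueError):
            trace_metrics([], frame_interval=0.5)


class TestPathSymmetry:
    def test_soma_swap_exchanges_direction_labels(self, det_params):
        p = SimParams(field_size=(32, 256), n_frames=100, fraction_motile=1.0,
                      p_pause=0.0, v_sd=0.0, particles_per_axon=4, seed=8)
        movie, gt = simulate_axon_movie(p)
        path = gt.paths[0]
        m1 = trace_metrics(extract_traces(movie, path, det_params),
                           movie.frame_interval)
        m2 = trace_metrics(extract_traces(movie, path.with_soma_swapped(),
                                          det_params), movie.frame_interval)
        assert m1.percent_anterograde == pytest.approx(m2.percent_retrograde)
        assert m1.percent_retrograde == pytest.approx(m2.percent_anterograde)
        assert m1.percent_motile == pytest.approx(m2.percent_motile)
        if m1.velocity_anterograde_um_s is not None:
            assert m1.velocity_anterograde_um_s == pytest.approx(
                m2.velocity_retrograde_um_s, rel=1e-6)

    def test_reversed_vertices_same_oriented_geometry(self):
        path = straight_path()
        flipped = AxonPath(path.vertices_px[::-1], soma_at_start=False)
        s = np.array([3.0, 17.0])
        assert np.allclose(path.point_at(s), flipped.point_at(s))


class TestDensity:
    def test_arithmetic(self):
        path = straight_path(length_px=500)   # 100 um at 0.2 um/px
        traces = [Trace(i, np.arange(3), np.full(3, 10.0 + i))
                  for i in range(5)]
        assert axon_density(traces, path, 0.2) == pytest.approx(0.05)

    def test_empty(self):
        assert axon_density([], straight_path(), 0.2) == 0.0

    def test_complete_detection_density(self, det_params):
        p = SimParams(field_size=(48, 256), n_frames=40, fraction_motile=0.0,
                      particles_per_axon=5, seed=12)
        movie, gt = simulate_axon_movie(p)
        traces = extract_traces(movie, gt.paths[0], det_params)
        full = [t for t in traces if len(t.frames) >= 30]
        d = axon_density(full, gt.paths[0], movie.pixel_size)
        assert d == pytest.approx(5 / gt.paths[0].length_um(movie.pixel_size),
                                  rel=1e-6)
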