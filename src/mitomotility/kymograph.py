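"""Single-axon kymograph analysis.

A kymograph resamples the movie along the axon centerline: one column per
pixel of arc length, one row per frame (time proceeding downward), with
anterograde position increasing to the right.  Per-mitochondrion traces are
obtained by projecting 2D detections onto the path and linking them in the
1D arc-length coordinate; each trace yields a direction label, a motility
flag, and a run velocity.

Conventions:

* a trace is motile when |net Δs| over the record exceeds the same 2 μm
  net-displacement threshold used by the 2D tracker;
* direction is the sign of net Δs (tie broken by the larger directional
  excursion), so anterograde% + retrograde% equals overall motile% exactly;
* the reported velocity is run speed: frame-to-frame steps of the smoothed
  trace, averaged over frames moving faster than ``pause_speed_um_s`` —
  pauses are excluded, matching the convention that "average velocity"
  tracks the speed while moving.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates, uniform_filter1d

from .geometry import AxonPath
from .movie import Movie
from .tracking import DetectionParams, detect_movie, _assign

__all__ = ["KymographMatrix", "Trace", "TraceMetrics", "build_kymograph",
           "extract_traces", "trace_metrics", "axon_density"]


@dataclass
class KymographMatrix:
    """Time (rows, downward) × arc-length position (columns, anterograde right)."""

    data: np.ndarray
    pos_scale_um: float    # μm per column
    time_scale_s: float    # s per row

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_positions(self) -> int:
        return self.data.shape[1]


@dataclass
class Trace:
    """One mitochondrion's path coordinate over time (μm from the soma)."""

    particle: int
    frames: np.ndarray
    s_um: np.ndarray
    motile: bool = False
    direction: str = "stationary"   # 'anterograde' | 'retrograde' | 'stationary'
    velocity_um_s: float | None = None

    @property
    def net_ds_um(self) -> float:
        return float(self.s_um[-1] - self.s_um[0]) if len(self.s_um) > 1 else 0.0


@dataclass
class TraceMetrics:
    """Axon-level motility readouts derived from traces."""

    n: int
    percent_motile: float
    percent_anterograde: float
    percent_retrograde: float
    velocity_anterograde_um_s: float | None
    velocity_retrograde_um_s: float | None
    n_anterograde: int
    n_retrograde: int


def build_kymograph(movie: Movie, path: AxonPath, band_width: int = 3
                    ) -> KymographMatrix:
    """Resample the movie along the axon into a kymograph matrix.

    For each frame and each 1-px arc-length sample, the value is the maximum
    intensity within ``band_width`` px perpendicular to the path (robust to
    the axon wobbling within the band).
    """
    if band_width < 1:
        raise ValueError("band_width must be >= 1")
    H, W = movie.frames.shape[1:]
    verts = path.oriented_vertices
    out_x = (verts[:, 0] < 0) | (verts[:, 0] > W - 1)
    out_y = (verts[:, 1] < 0) | (verts[:, 1] > H - 1)
    if np.any(out_x | out_y):
        bad = int(np.argmax(out_x | out_y))
        raise ValueError(f"axon path vertex {bad} at {tuple(verts[bad])} "
                         f"lies outside the {W}x{H} frame")
    n_cols = int(np.ceil(path.length_px))
    s = np.arange(n_cols) + 0.5
    centers = path.point_at(s)            # (n_cols, 2) as (x, y)
    tangents = path.tangent_at(s)
    normals = np.stack([-tangents[:, 1], tangents[:, 0]], axis=1)
    offsets = np.arange(-band_width, band_width + 1)
    # sample grid: (n_offsets, n_cols, 2)
    pts = centers[None, :, :] + offsets[:, None, None] * normals[None, :, :]
    coords = np.stack([pts[..., 1].ravel(), pts[..., 0].ravel()])  # (y, x)
    data = np.empty((movie.n_frames, n_cols))
    for t in range(movie.n_frames):
        vals = map_coordinates(movie.frames[t].astype(float), coords,
                               order=1, mode="nearest")
        data[t] = vals.reshape(len(offsets), n_cols).max(axis=0)
    return KymographMatrix(data, pos_scale_um=movie.pixel_size,
                           time_scale_s=movie.frame_interval)


def extract_traces(movie: Movie, path: AxonPath,
                   params: DetectionParams | None = None,
                   band_width: float = 4.0) -> list[Trace]:
    """Detect, project onto the axon, and link traces in 1D.

    Detections farther than ``band_width`` px from the path are discarded.
    Linking uses the same gated optimal assignment as the 2D tracker, on the
    arc-length coordinate.
    """
    params = params or DetectionParams()
    detections = detect_movie(movie, params)
    gate_px = params.link_gate_um / movie.pixel_size

    per_frame_s = []
    for dets in detections:
        if dets:
            xy = np.array([[d.x, d.y] for d in dets])
            s, dist = path.project(xy)
            s = np.sort(s[dist <= band_width])
        else:
            s = np.empty(0)
        per_frame_s.append(s)

    next_id = 0
    active, finished = [], []
    for t, s_vals in enumerate(per_frame_s):
        still = []
        for tr in active:
            if t - tr["last_frame"] > params.gap_close_frames + 1:
                finished.append(tr)
            else:
                still.append(tr)
        active = still
        cur = np.column_stack([s_vals, np.zeros_like(s_vals)])
        prev = np.array([[tr["s"][-1], 0.0] for tr in active]).reshape(-1, 2)
        gaps = np.array([t - tr["last_frame"] for tr in active], dtype=float)
        gates = gate_px * np.maximum(gaps, 1.0)
        match, unmatched = _assign(prev, cur, gates)
        for r, c in match.items():
            active[r]["frames"].append(t)
            active[r]["s"].append(s_vals[c])
            active[r]["last_frame"] = t
        for c in unmatched:
            active.append({"id": next_id, "frames": [t], "s": [s_vals[c]],
                           "last_frame": t})
            next_id += 1
    finished.extend(active)
    finished.sort(key=lambda tr: tr["id"])
    traces = [Trace(tr["id"], np.asarray(tr["frames"]),
                    np.asarray(tr["s"]) * movie.pixel_size)
              for tr in finished]
    for trace in traces:
        _classify_trace(trace, params.motile_threshold_um)
    return traces


def _classify_trace(trace: Trace, motile_threshold_um: float) -> None:
    s = trace.s_um
    if len(s) < 2:
        trace.motile = False
        trace.direction = "stationary"
        return
    net = s[-1] - s[0]
    trace.motile = bool(abs(net) >= motile_threshold_um)
    if not trace.motile:
        trace.direction = "stationary"
    elif net > 0:
        trace.direction = "anterograde"
    elif net < 0:
        trace.direction = "retrograde"
    else:
        # net exactly 0 but above-threshold|net| cannot happen; tie-break by
        # the larger directional excursion for robustness
        up = float(np.max(s - s[0]))
        down = float(np.max(s[0] - s))
        trace.direction = "anterograde" if up >= down else "retrograde"


def _run_speed(trace: Trace, frame_interval: float, pause_speed_um_s: float,
               smooth_window: int) -> float | None:
    """Mean speed over moving frames of the smoothed arc-length trace."""
    s = trace.s_um
    if len(s) < 2:
        return None
    w = max(1, min(smooth_window, len(s)))
    s_sm = uniform_filter1d(s, size=w, mode="nearest")
    steps = np.abs(np.diff(s_sm))
    dts = np.diff(trace.frames) * frame_interval
    speeds = steps / dts
    moving = speeds >= pause_speed_um_s
    if not moving.any():
        # slow creep below the pause threshold: fall back to total-time speed
        return float(steps.sum() / dts.sum())
    return float(steps[moving].sum() / dts[moving].sum())


def trace_metrics(traces: list[Trace], frame_interval: float,
                  pause_speed_um_s: float = 0.05,
                  smooth_window: int = 5) -> TraceMetrics:
    """Percent motile per direction and directional run velocities.

    Directions partition the motile traces, so the overall percent motile is
    exactly the sum of the anterograde and retrograde percentages.  A
    direction with no motile traces reports its velocity as ``None`` rather
    than zero.
    """
    if not traces:
        raise ValueError("trace_metrics needs at least one trace")
    n = len(traces)
    antero = [tr for tr in traces if tr.motile and tr.direction == "anterograde"]
    retro = [tr for tr in traces if tr.motile and tr.direction == "retrograde"]

    def mean_speed(group):
        vals = [_run_speed(tr, frame_interval, pause_speed_um_s, smooth_window)
                for tr in group]
        vals = [v for v in vals if v is not None]
        return float(np.mean(vals)) if vals else None

    v_a, v_r = mean_speed(antero), mean_speed(retro)
    for tr in traces:
        if tr.motile:
            tr.velocity_um_s = _run_speed(tr, frame_interval,
                                          pause_speed_um_s, smooth_window)
    return TraceMetrics(
        n=n,
        percent_motile=100.0 * (len(antero) + len(retro)) / n,
        percent_anterograde=100.0 * len(antero) / n,
        percent_retrograde=100.0 * len(retro) / n,
        velocity_anterograde_um_s=v_a,
        velocity_retrograde_um_s=v_r,
        n_anterograde=len(antero),
        n_retrograde=len(retro),
    )


def axon_density(traces: list[Trace], path: AxonPath, pixel_size: float
                 ) -> float:
    """Mitochondria per μm of axon: distinct traces / path length."""
    length = path.length_um(pixel_size)
    if length <= 0:
        raise ValueError("axon path has zero length")
    return len(traces) / length
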