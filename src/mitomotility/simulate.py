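"""Synthetic time-lapse movie generator with exact ground truth.

Three imaging regimes are emulated:

* single axon segments (~70–115 μm) imaged for 3 minutes at 2 Hz, the
  kymograph regime;
* multi-axon fields imaged for 30 frames, the high-content screening regime
  (one frame per second, ~10 mitochondria per axon-length of ~0.1/μm);
* reticulum-style cells (HeLa-like) where mitochondria form a connected
  network and only bulk pixel statistics are informative.

Mitochondria follow a three-state kinetic model: a particle is either
stationary for the whole movie, or motile with a fixed direction
(anterograde = away from the soma, retrograde = toward it) and a constant
run speed drawn from a truncated normal.  Motile particles alternate
between moving and paused according to a two-state Markov chain whose
stationary pause probability is ``p_pause`` and whose mean pause duration is
``mean_pause_frames`` (run/pause kinetics of axonal mitochondria are not
standardised; the Markov chain is the simplest model that reproduces
percent-motile and run-velocity readouts).  Stationary particles jitter
with sub-resolution amplitude around a fixed anchor.

Particles are rendered as isotropic Gaussian point-spread functions and
Poisson shot noise is applied over a constant background.  The same seed
always produces a bit-identical movie and ground truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import AxonPath
from .movie import Movie

__all__ = [
    "SimParams", "GroundTruth",
    "simulate_axon_movie", "simulate_field_movie", "simulate_reticulum_movie",
    "simulate_dose_response", "simulate_well_distances",
    "occupancy_flip_fraction",
]


@dataclass
class SimParams:
    """Simulation parameters; defaults emulate the single-axon regime.

    Velocities default to control-condition axonal run speeds
    (anterograde ~0.10 μm/s, retrograde ~0.14 μm/s) and a ~10% motile
    fraction, the baseline of untreated neurons.
    """

    field_size: tuple = (64, 448)       # (H, W) px
    pixel_size: float = 0.2             # μm / px
    frame_interval: float = 0.5         # s  (2 Hz)
    n_frames: int = 360                 # 3 min at 2 Hz
    n_axons: int = 1
    particles_per_axon: int = 8
    fraction_motile: float = 0.10
    v_antero_mean: float = 0.10         # μm/s
    v_retro_mean: float = 0.14          # μm/s
    v_sd: float = 0.02                  # μm/s, between-particle spread
    p_pause: float = 0.10               # stationary probability of the pause state
    psf_sigma: float = 1.2              # px
    photons_per_particle: float = 800.0
    background: float = 20.0            # counts / px
    seed: int = 0
    # model extras
    p_anterograde: float = 0.5          # direction split among motile particles
    mean_pause_frames: float = 4.0      # geometric mean pause duration
    jitter_px: float = 0.3              # stationary jitter SD, sub-resolution
    displacement_rate: float = 0.02     # μm/s, reticulum segment translation

    def __post_init__(self):
        if not (0.0 <= self.fraction_motile <= 1.0):
            raise ValueError("fraction_motile must be in [0, 1]")
        if not (0.0 <= self.p_pause < 1.0):
            raise ValueError("p_pause must be in [0, 1)")
        for name in ("pixel_size", "frame_interval", "photons_per_particle",
                     "mean_pause_frames"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.psf_sigma < 0.5:
            raise ValueError("psf_sigma < 0.5 px is unresolvable on the pixel grid")
        if self.background < 0 or self.v_sd < 0 or self.jitter_px < 0:
            raise ValueError("background, v_sd and jitter_px must be non-negative")
        if min(self.v_antero_mean, self.v_retro_mean) < 0:
            raise ValueError("velocities must be non-negative")
        self.field_size = (int(self.field_size[0]), int(self.field_size[1]))

    @classmethod
    def field_regime(cls, **overrides) -> "SimParams":
        """High-content screening regime: 30 frames, multi-axon field.

        One frame per second gives the ~30 s per-field imaging window of a
        plate screen; velocities are mid-range axonal run speeds.
        """
        base = dict(
            field_size=(256, 256), pixel_size=0.3, frame_interval=1.0,
            n_frames=30, n_axons=10, particles_per_axon=8,
            v_antero_mean=0.15, v_retro_mean=0.15, v_sd=0.03,
        )
        base.update(overrides)
        return cls(**base)

    @classmethod
    def reticulum_regime(cls, **overrides) -> "SimParams":
        """Reticular-cell regime: 3 min movie of a connected network."""
        base = dict(
            field_size=(128, 128), pixel_size=0.2, frame_interval=2.0,
            n_frames=90, n_axons=1, particles_per_axon=0,
        )
        base.update(overrides)
        return cls(**base)

    def replace(self, **changes) -> "SimParams":
        return dataclasses.replace(self, **changes)


@dataclass
class GroundTruth:
    """Exact per-particle states and kinematics behind a simulated movie.

    ``particles`` has one row per particle (id, axon, motile flag, direction
    in {+1, -1, 0}, run speed, true integrated path length and net
    displacement in μm).  ``positions`` has one row per particle per frame
    (arc-length coordinate s in μm from the soma, continuous pixel-center
    x/y, and whether the particle was in the moving state that frame).
    """

    particles: pd.DataFrame
    positions: pd.DataFrame
    paths: list
    pixel_size: float
    frame_interval: float
    jitter_bound_um: float = 0.0
    occupancy: np.ndarray | None = None   # (t, y, x) bool, reticulum only

    @property
    def n_particles(self) -> int:
        return len(self.particles)

    @property
    def percent_motile(self) -> float:
        return 100.0 * float(self.particles["motile"].mean())


# ---------------------------------------------------------------------------
# kinematics

def _truncated_normal(rng, mean, sd, size):
    """Normal(mean, sd) truncated at 0 by rejection."""
    out = rng.normal(mean, sd, size=size)
    bad = out < 0
    while np.any(bad):
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = out < 0
    return out


def _pause_states(rng, n_particles, n_frames, p_pause, mean_pause_frames):
    """Boolean (n_particles, n_frames) array: True where moving.

    Two-state Markov chain with stationary pause probability ``p_pause`` and
    geometric pause durations of mean ``mean_pause_frames``.
    """
    if p_pause == 0:
        return np.ones((n_particles, n_frames), dtype=bool)
    leave_pause = 1.0 / mean_pause_frames
    enter_pause = leave_pause * p_pause / (1.0 - p_pause)
    enter_pause = min(enter_pause, 1.0)
    moving = np.empty((n_particles, n_frames), dtype=bool)
    moving[:, 0] = rng.random(n_particles) >= p_pause
    for t in range(1, n_frames):
        u = rng.random(n_particles)
        prev = moving[:, t - 1]
        moving[:, t] = np.where(prev, u >= enter_pause, u < leave_pause)
    return moving


def _simulate_particles_on_path(params: SimParams, path: AxonPath, rng,
                                axon_index: int, id_offset: int):
    """Simulate one axon's particles; returns (particle df, positions df)."""
    n = params.particles_per_axon
    nf = params.n_frames
    dt = params.frame_interval
    L_um = path.length_um(params.pixel_size)
    if n == 0:
        empty_particles = pd.DataFrame({
            "particle": pd.Series(dtype=int), "axon": pd.Series(dtype=int),
            "motile": pd.Series(dtype=bool), "direction": pd.Series(dtype=int),
            "speed_um_s": pd.Series(dtype=float),
            "s0_um": pd.Series(dtype=float),
            "path_length_um": pd.Series(dtype=float),
            "net_displacement_um": pd.Series(dtype=float)})
        empty_positions = pd.DataFrame({
            "particle": pd.Series(dtype=int), "frame": pd.Series(dtype=int),
            "s_um": pd.Series(dtype=float), "x_px": pd.Series(dtype=float),
            "y_px": pd.Series(dtype=float), "moving": pd.Series(dtype=bool)})
        return empty_particles, empty_positions

    motile = rng.random(n) < params.fraction_motile
    antero = rng.random(n) < params.p_anterograde
    direction = np.where(motile, np.where(antero, 1, -1), 0)
    v_mean = np.where(antero, params.v_antero_mean, params.v_retro_mean)
    speed = np.where(motile, _truncated_normal(rng, v_mean, params.v_sd, n), 0.0)

    # jittered-grid anchors keep particles separated along the axon
    slot = L_um / n
    s0 = (np.arange(n) + 0.1 + 0.8 * rng.random(n)) * slot

    moving = _pause_states(rng, n, nf, params.p_pause, params.mean_pause_frames)
    moving[~motile] = False

    # arc-length trajectories; shift motile starts so runs stay on the path
    steps = moving * (direction[:, None] * speed[:, None] * dt)
    total_drift = steps.sum(axis=1)
    margin = min(1.0, 0.1 * L_um)
    lo = np.maximum(margin, margin - np.minimum(total_drift, 0.0))
    hi = np.minimum(L_um - margin, L_um - margin - np.maximum(total_drift, 0.0))
    s0 = np.clip(s0, lo, np.maximum(hi, lo))
    s = s0[:, None] + np.concatenate(
        [np.zeros((n, 1)), np.cumsum(steps, axis=1)[:, :-1]], axis=1)
    s = np.clip(s, 0.0, L_um)

    # 2D positions: motile on the path; stationary anchored with jitter
    xy = np.empty((n, nf, 2))
    for i in range(n):
        xy[i] = path.point_at(s[i] / params.pixel_size)
    jitter = rng.normal(0.0, params.jitter_px, size=(n, nf, 2))
    np.clip(jitter, -3 * params.jitter_px, 3 * params.jitter_px, out=jitter)
    xy[~motile] += jitter[~motile]
    # keep stationary ground truth consistent: s of jittered anchor
    H, W = params.field_size
    xy[..., 0] = np.clip(xy[..., 0], 0.0, W - 1.0)
    xy[..., 1] = np.clip(xy[..., 1], 0.0, H - 1.0)

    step_len_um = np.linalg.norm(np.diff(xy, axis=1), axis=2) * params.pixel_size
    path_len = step_len_um.sum(axis=1)
    net_disp = np.linalg.norm(xy[:, -1] - xy[:, 0], axis=1) * params.pixel_size

    ids = id_offset + np.arange(n)
    particles = pd.DataFrame({
        "particle": ids,
        "axon": axon_index,
        "motile": motile,
        "direction": direction,
        "speed_um_s": speed,
        "s0_um": s0,
        "path_length_um": path_len,
        "net_displacement_um": net_disp,
    })
    positions = pd.DataFrame({
        "particle": np.repeat(ids, nf),
        "frame": np.tile(np.arange(nf), n),
        "s_um": s.ravel(),
        "x_px": xy[..., 0].ravel(),
        "y_px": xy[..., 1].ravel(),
        "moving": moving.ravel(),
    })
    return particles, positions


# ---------------------------------------------------------------------------
# rendering

def _render_movie(positions: pd.DataFrame, params: SimParams, rng) -> np.ndarray:
    """Render Gaussian PSFs at true positions, add Poisson noise."""
    H, W = params.field_size
    nf = params.n_frames
    sig = params.psf_sigma
    amp = params.photons_per_particle / (2.0 * np.pi * sig**2)
    half = int(np.ceil(4 * sig)) + 1
    expected = np.full((nf, H, W), float(params.background))
    frames_idx = positions["frame"].to_numpy()
    xs = positions["x_px"].to_numpy()
    ys = positions["y_px"].to_numpy()
    for t, x, y in zip(frames_idx, xs, ys):
        x0, x1 = int(np.floor(x)) - half, int(np.floor(x)) + half + 1
        y0, y1 = int(np.floor(y)) - half, int(np.floor(y)) + half + 1
        x0c, x1c = max(x0, 0), min(x1, W)
        y0c, y1c = max(y0, 0), min(y1, H)
        if x0c >= x1c or y0c >= y1c:
            continue
        gx = np.arange(x0c, x1c) - x
        gy = np.arange(y0c, y1c) - y
        g = np.exp(-(gy[:, None] ** 2 + gx[None, :] ** 2) / (2 * sig**2))
        expected[t, y0c:y1c, x0c:x1c] += amp * g
    return rng.poisson(expected).astype(np.uint16)


def _wobbly_chord(rng, H, W, margin, horizontal=False):
    """A smooth polyline crossing the field, as an (N, 2) (x, y) array."""
    if horizontal:
        p0 = np.array([margin, H / 2 + rng.uniform(-H / 6, H / 6)])
        p1 = np.array([W - margin, H / 2 + rng.uniform(-H / 6, H / 6)])
    else:
        theta = rng.uniform(0, np.pi)
        d = np.array([np.cos(theta), np.sin(theta)])
        c = np.array([W / 2, H / 2]) + rng.uniform(-0.2, 0.2, 2) * [W, H]
        # extend to the margin box
        tmax = min(W, H)  # generous; clipped below
        p0, p1 = c - tmax * d, c + tmax * d
        box_lo = np.array([margin, margin])
        box_hi = np.array([W - margin, H - margin])
        # clip the segment to the box by shrinking parameters
        def clip_t(p, q):
            t0, t1 = 0.0, 1.0
            for k in range(2):
                dk = q[k] - p[k]
                if abs(dk) < 1e-12:
                    if not (box_lo[k] <= p[k] <= box_hi[k]):
                        return None
                    continue
                ta = (box_lo[k] - p[k]) / dk
                tb = (box_hi[k] - p[k]) / dk
                ta, tb = min(ta, tb), max(ta, tb)
                t0, t1 = max(t0, ta), min(t1, tb)
            return (t0, t1) if t0 < t1 else None
        tt = clip_t(p0, p1)
        if tt is None:  # degenerate, fall back to horizontal chord
            return _wobbly_chord(rng, H, W, margin, horizontal=True)
        p0, p1 = p0 + tt[0] * (p1 - p0), p0 + tt[1] * (p1 - p0)
    length = np.linalg.norm(p1 - p0)
    n_pts = max(int(length // 12), 2) + 1
    t = np.linspace(0, 1, n_pts)
    base = p0[None, :] + t[:, None] * (p1 - p0)[None, :]
    normal = np.array([-(p1 - p0)[1], (p1 - p0)[0]]) / max(length, 1e-9)
    amp = rng.uniform(1.0, 3.5)
    lam = rng.uniform(0.5, 1.5)
    phase = rng.uniform(0, 2 * np.pi)
    wobble = amp * np.sin(2 * np.pi * lam * t + phase)
    pts = base + wobble[:, None] * normal[None, :]
    pts[:, 0] = np.clip(pts[:, 0], margin * 0.5, W - margin * 0.5)
    pts[:, 1] = np.clip(pts[:, 1], margin * 0.5, H - margin * 0.5)
    return pts


def _jitter_bound_um(params: SimParams) -> float:
    """Upper bound on a stationary particle's true integrated path length."""
    per_step = 2 * 3 * params.jitter_px * np.sqrt(2) * params.pixel_size
    return (params.n_frames - 1) * per_step


def simulate_axon_movie(params: SimParams) -> tuple[Movie, GroundTruth]:
    """Simulate a single axon segment spanning the field.

    The axon runs left to right with the soma at the left edge, so
    anterograde movement is rightward (increasing x), matching the standard
    kymograph display convention.
    """
    rng = np.random.default_rng(params.seed)
    H, W = params.field_size
    path = AxonPath(_wobbly_chord(rng, H, W, margin=6.0, horizontal=True),
                    soma_at_start=True)
    particles, positions = _simulate_particles_on_path(params, path, rng, 0, 0)
    frames = _render_movie(positions, params, rng)
    movie = Movie(frames, params.pixel_size, params.frame_interval)
    gt = GroundTruth(particles, positions, [path], params.pixel_size,
                     params.frame_interval, _jitter_bound_um(params))
    return movie, gt


def simulate_field_movie(params: SimParams) -> tuple[Movie, GroundTruth]:
    """Simulate a multi-axon field (screening regime, default 30 frames)."""
    if params.n_axons < 1:
        raise ValueError("n_axons must be >= 1")
    rng = np.random.default_rng(params.seed)
    H, W = params.field_size
    all_particles, all_positions, paths = [], [], []
    for a in range(params.n_axons):
        path = AxonPath(_wobbly_chord(rng, H, W, margin=6.0), soma_at_start=True)
        paths.append(path)
        p, pos = _simulate_particles_on_path(
            params, path, rng, a, a * params.particles_per_axon)
        all_particles.append(p)
        all_positions.append(pos)
    particles = pd.concat(all_particles, ignore_index=True)
    positions = pd.concat(all_positions, ignore_index=True)
    frames = _render_movie(positions, params, rng)
    movie = Movie(frames, params.pixel_size, params.frame_interval)
    gt = GroundTruth(particles, positions, paths, params.pixel_size,
                     params.frame_interval, _jitter_bound_um(params))
    return movie, gt


# ---------------------------------------------------------------------------
# reticulum

def _disk_offsets(radius: int) -> np.ndarray:
    r = np.arange(-radius, radius + 1)
    yy, xx = np.meshgrid(r, r, indexing="ij")
    keep = yy**2 + xx**2 <= radius**2
    return np.stack([yy[keep], xx[keep]], axis=1)


def simulate_reticulum_movie(params: SimParams) -> tuple[Movie, GroundTruth]:
    """Simulate a connected tubular network whose branches translate.

    Each branch of the network slides along its own random direction at
    ``displacement_rate`` μm/s, reflecting at a ±10 px excursion so the
    network stays in the field.  Ground truth records the noise-free binary
    occupancy of every pixel in every frame.
    """
    rng = np.random.default_rng(params.seed)
    H, W = params.field_size
    nf = params.n_frames
    center = np.array([H / 2.0, W / 2.0])
    n_branches = 8
    tube_radius = 2
    excursion_px = 10.0

    # grow branches as persistent random walks from existing nodes
    nodes = [center.copy()]
    branches = []
    for _ in range(n_branches):
        start = nodes[rng.integers(len(nodes))]
        ang = rng.uniform(0, 2 * np.pi)
        pts = [start.copy()]
        for _ in range(rng.integers(20, 40)):
            ang += rng.normal(0, 0.3)
            nxt = pts[-1] + 1.5 * np.array([np.sin(ang), np.cos(ang)])
            nxt[0] = np.clip(nxt[0], 14, H - 15)
            nxt[1] = np.clip(nxt[1], 14, W - 15)
            pts.append(nxt)
        branch = np.array(pts)          # (M, 2) in (y, x)
        branches.append(branch)
        nodes.append(branch[-1])

    rate_px = params.displacement_rate * params.frame_interval / params.pixel_size
    dirs = rng.normal(size=(n_branches, 2))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)

    disk = _disk_offsets(tube_radius)
    occupancy = np.zeros((nf, H, W), dtype=bool)
    for t in range(nf):
        # triangle-wave excursion: slide out to 2*excursion and back
        travel = rate_px * t
        if excursion_px > 0:
            phase = travel % (4 * excursion_px)
            offset_mag = phase if phase <= 2 * excursion_px else 4 * excursion_px - phase
        else:
            offset_mag = travel
        for b, branch in enumerate(branches):
            shifted = branch + offset_mag * dirs[b]
            px = np.round(shifted).astype(int)
            cells = (px[:, None, :] + disk[None, :, :]).reshape(-1, 2)
            keep = ((cells[:, 0] >= 0) & (cells[:, 0] < H)
                    & (cells[:, 1] >= 0) & (cells[:, 1] < W))
            cells = cells[keep]
            occupancy[t, cells[:, 0], cells[:, 1]] = True

    from scipy.ndimage import gaussian_filter
    amp = params.photons_per_particle / (2.0 * np.pi * params.psf_sigma**2)
    expected = np.empty((nf, H, W))
    for t in range(nf):
        expected[t] = params.background + amp * gaussian_filter(
            occupancy[t].astype(float), params.psf_sigma)
    frames = rng.poisson(expected).astype(np.uint16)
    movie = Movie(frames, params.pixel_size, params.frame_interval)
    particles = pd.DataFrame(
        {"particle": [], "axon": [], "motile": [], "direction": [],
         "speed_um_s": [], "s0_um": [], "path_length_um": [],
         "net_displacement_um": []})
    positions = pd.DataFrame(
        {"particle": [], "frame": [], "s_um": [], "x_px": [], "y_px": [],
         "moving": []})
    gt = GroundTruth(particles, positions, [], params.pixel_size,
                     params.frame_interval, 0.0, occupancy=occupancy)
    return movie, gt


def occupancy_flip_fraction(occupancy: np.ndarray) -> float:
    """Fraction of ever-occupied pixels whose occupancy changes at least once."""
    footprint = occupancy.any(axis=0)
    if not footprint.any():
        return 0.0
    flips = (occupancy[1:] != occupancy[:-1]).any(axis=0)
    return float(flips[footprint].mean())


# ---------------------------------------------------------------------------
# tabular simulators

def simulate_dose_response(ec50: float, hill: float, top: float, bottom: float,
                           concentrations, noise_sd: float = 0.0,
                           n_rep: int = 1, seed: int = 0) -> pd.DataFrame:
    """Sample responses from a four-parameter logistic plus Gaussian noise.

    ``ec50`` and ``concentrations`` in μM; responses on the same scale as
    ``top``/``bottom`` (typically percent of maximum activity).
    """
    conc = np.asarray(concentrations, dtype=float)
    if ec50 <= 0 or np.any(conc <= 0):
        raise ValueError("ec50 and concentrations must be positive")
    rng = np.random.default_rng(seed)
    logc = np.log10(conc)
    mu = bottom + (top - bottom) / (1 + 10 ** ((np.log10(ec50) - logc) * hill))
    rows = []
    for rep in range(n_rep):
        y = mu + rng.normal(0.0, noise_sd, size=len(conc))
        rows.append(pd.DataFrame({
            "concentration_uM": conc, "replicate": rep, "response": y}))
    return pd.concat(rows, ignore_index=True)


def simulate_well_distances(n_particles: int, fraction_motile: float,
                            rng=None, *, n_frames: int = 30,
                            frame_interval: float = 1.0,
                            v_mean: float = 0.15, v_sd: float = 0.03,
                            p_pause: float = 0.10,
                            mean_pause_frames: float = 4.0,
                            jitter_um: float = 0.09,
                            loc_noise_um: float = 0.045,
                            smooth_window: int = 5) -> pd.DataFrame:
    """Sample per-particle measured integrated distances for one well.

    Runs the same kinetic model as the movie simulator at the trajectory
    level (no image rendering), adding localisation noise to each frame's
    position, so plate-scale screening statistics can be exercised with
    realistic particle counts (the screening regime tracks ~10,000
    mitochondria per well).  Returns one row per particle with the measured
    integrated distance, measured net displacement, and the true motile flag.
    """
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    n = int(n_particles)
    motile = rng.random(n) < fraction_motile
    speed = _truncated_normal(rng, v_mean, v_sd, n)
    moving = _pause_states(rng, n, n_frames, p_pause, mean_pause_frames)
    moving[~motile] = False
    steps = moving * (speed[:, None] * frame_interval)   # along-path, μm
    s = np.concatenate([np.zeros((n, 1)), np.cumsum(steps, axis=1)], axis=1)[:, :n_frames]
    pos = np.zeros((n, n_frames, 2))
    pos[..., 0] = s
    jitter = rng.normal(0.0, jitter_um, size=(n, n_frames, 2))
    pos[~motile] += jitter[~motile]
    pos += rng.normal(0.0, loc_noise_um, size=pos.shape)
    net = np.linalg.norm(pos[:, -1] - pos[:, 0], axis=1)
    if smooth_window > 1:
        from scipy.ndimage import uniform_filter1d
        w = min(int(smooth_window), n_frames)
        pos = uniform_filter1d(pos, size=w, axis=1, mode="nearest")
    step_len = np.linalg.norm(np.diff(pos, axis=1), axis=2)
    distances = step_len.sum(axis=1)
    return pd.DataFrame({
        "distance_um": distances,
        "net_displacement_um": net,
        "true_motile": motile,
    })
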