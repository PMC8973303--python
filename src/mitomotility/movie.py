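"""The universal imaging container: a calibrated time-lapse movie.

Movies are stored on disk as multi-page TIFF stacks with a JSON sidecar
(`<stem>.json`) carrying the two pieces of calibration every downstream
metric needs: pixel size (μm/px) and frame interval (s).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

SIDECAR_KEYS = ("pixel_size_um", "frame_interval_s")


@dataclass
class Movie:
    """A (t, y, x) intensity stack with spatial and temporal calibration."""

    frames: np.ndarray
    pixel_size: float       # μm per pixel
    frame_interval: float   # seconds between frames

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a 3D (t, y, x) array")
        if self.frames.shape[0] < 2:
            raise ValueError("a movie needs at least 2 frames")
        if np.any(self.frames < 0):
            raise ValueError("intensities must be non-negative")
        if not (self.pixel_size > 0 and self.frame_interval > 0):
            raise ValueError("pixel_size and frame_interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self):
        return self.frames.shape

    @property
    def duration(self) -> float:
        """Total imaging duration in seconds, (n_frames - 1) intervals."""
        return (self.n_frames - 1) * self.frame_interval


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_movie(movie: Movie, path) -> Path:
    """Write a multi-page TIFF plus its calibration sidecar JSON."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, movie.frames, photometric="minisblack")
    meta = {
        "pixel_size_um": movie.pixel_size,
        "frame_interval_s": movie.frame_interval,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def read_movie(path, pixel_size: float | None = None,
               frame_interval: float | None = None) -> Movie:
    """Read a TIFF stack; calibration from the sidecar or explicit overrides.

    Explicit ``pixel_size`` / ``frame_interval`` take precedence over the
    sidecar.  If the sidecar is missing, both must be supplied.
    """
    path = Path(path)
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        raise ValueError("a movie needs at least 2 frames; got a single page")
    sidecar = _sidecar_path(path)
    meta = {}
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    px = pixel_size if pixel_size is not None else meta.get("pixel_size_um")
    dt = frame_interval if frame_interval is not None else meta.get("frame_interval_s")
    if px is None or dt is None:
        raise FileNotFoundError(
            f"no calibration sidecar at {sidecar}; supply pixel size and frame "
            "interval explicitly (CLI: --pixel-size / --frame-interval)"
        )
    return Movie(frames=frames, pixel_size=float(px), frame_interval=float(dt))
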