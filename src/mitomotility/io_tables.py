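"""Tabular file formats: tracks, traces, axon paths, plate maps.

Conventions used in every file: coordinates are 0-based continuous pixel
units; arc lengths and distances are μm; times are seconds.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import AxonPath
from .kymograph import Trace
from .tracking import Track, integrated_distance, net_displacement

FLOAT_FMT = "%.9g"   # stable text representation for reproducible outputs

PLATEMAP_COLUMNS = ["well", "compound", "concentration_uM", "replicate",
                    "is_vehicle"]


def write_csv(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=FLOAT_FMT)
    return path


def tracks_to_dataframe(tracks: list[Track], pixel_size: float) -> pd.DataFrame:
    """One row per track point, with per-step distance in μm."""
    rows = []
    for tr in tracks:
        step = np.concatenate(
            [[0.0], np.hypot(np.diff(tr.xs), np.diff(tr.ys)) * pixel_size])
        for i in range(len(tr)):
            rows.append((tr.particle, int(tr.frames[i]), tr.xs[i], tr.ys[i],
                         step[i]))
    return pd.DataFrame(rows, columns=["particle", "frame", "x_px", "y_px",
                                       "step_um"])


def track_summaries_to_dataframe(tracks: list[Track], pixel_size: float
                                 ) -> pd.DataFrame:
    rows = []
    for tr in tracks:
        rows.append({
            "particle": tr.particle,
            "n_points": len(tr),
            "first_frame": int(tr.frames[0]),
            "last_frame": int(tr.frames[-1]),
            "integrated_distance_um": integrated_distance(tr, pixel_size),
            "net_displacement_um": net_displacement(tr, pixel_size),
            "motile": bool(tr.motile) if tr.motile is not None else False,
        })
    return pd.DataFrame(rows)


def traces_to_dataframe(traces: list[Trace]) -> pd.DataFrame:
    rows = []
    for tr in traces:
        for f, s in zip(tr.frames, tr.s_um):
            rows.append((tr.particle, int(f), s, tr.direction, tr.motile))
    return pd.DataFrame(rows, columns=["particle", "frame", "s_um",
                                       "direction", "motile"])


def write_axon_path_csv(path_obj: AxonPath, path) -> Path:
    """Vertices as x_px, y_px rows; soma_end flags the soma-end vertex."""
    v = path_obj.vertices_px
    soma = np.zeros(len(v), dtype=int)
    soma[0 if path_obj.soma_at_start else -1] = 1
    df = pd.DataFrame({"x_px": v[:, 0], "y_px": v[:, 1], "soma_end": soma})
    return write_csv(df, path)


def read_axon_path_csv(path) -> AxonPath:
    df = pd.read_csv(path)
    for col in ("x_px", "y_px", "soma_end"):
        if col not in df.columns:
            raise ValueError(f"axon path CSV missing column {col!r}")
    v = df[["x_px", "y_px"]].to_numpy(dtype=float)
    flags = df["soma_end"].to_numpy()
    if flags[0]:
        soma_at_start = True
    elif flags[-1]:
        soma_at_start = False
    else:
        raise ValueError("soma_end flag must mark the first or last vertex")
    return AxonPath(v, soma_at_start=soma_at_start)


def read_platemap(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in PLATEMAP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"plate map is missing columns: {missing}; expected "
                         f"{PLATEMAP_COLUMNS}")
    df["is_vehicle"] = df["is_vehicle"].astype(bool)
    return df
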