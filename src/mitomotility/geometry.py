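"""Polyline geometry for axon paths.

An axon is represented as a polyline in pixel coordinates.  Arc length along
the path, measured from the soma end, is the 1D coordinate used by kymograph
analysis; by convention anterograde transport means increasing arc length
(movement away from the soma).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def _as_vertices(vertices) -> np.ndarray:
    v = np.asarray(vertices, dtype=float)
    if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 2:
        raise ValueError("polyline needs an (N>=2, 2) array of (x, y) vertices")
    return v


def polyline_cumlength(vertices: np.ndarray) -> np.ndarray:
    """Cumulative arc length (px) at each vertex, starting at 0."""
    seg = np.linalg.norm(np.diff(vertices, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def point_at_arclength(vertices: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Interpolate (x, y) at arc length(s) ``s`` (px) along the polyline."""
    cum = polyline_cumlength(vertices)
    s = np.clip(np.atleast_1d(np.asarray(s, dtype=float)), 0.0, cum[-1])
    idx = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(cum) - 2)
    seg_len = cum[idx + 1] - cum[idx]
    t = np.where(seg_len > 0, (s - cum[idx]) / np.where(seg_len > 0, seg_len, 1.0), 0.0)
    return vertices[idx] + t[:, None] * (vertices[idx + 1] - vertices[idx])


def tangent_at_arclength(vertices: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Unit tangent vector at arc length(s) ``s`` (px)."""
    cum = polyline_cumlength(vertices)
    s = np.clip(np.atleast_1d(np.asarray(s, dtype=float)), 0.0, cum[-1])
    idx = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(cum) - 2)
    d = vertices[idx + 1] - vertices[idx]
    n = np.linalg.norm(d, axis=1, keepdims=True)
    return d / np.where(n > 0, n, 1.0)


def project_onto_polyline(vertices: np.ndarray, points: np.ndarray):
    """Project points onto the polyline.

    Returns ``(s, dist)``: arc length of the nearest point on the path (px,
    from the first vertex) and the perpendicular distance (px).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    a = vertices[:-1]                       # (M, 2)
    d = vertices[1:] - a                    # (M, 2)
    seg_len2 = np.einsum("ij,ij->i", d, d)
    seg_len2 = np.where(seg_len2 > 0, seg_len2, 1.0)
    # (N, M) parameter of the foot point on each segment
    w = pts[:, None, :] - a[None, :, :]
    t = np.clip(np.einsum("nmj,mj->nm", w, d) / seg_len2[None, :], 0.0, 1.0)
    foot = a[None, :, :] + t[..., None] * d[None, :, :]
    dist2 = np.sum((pts[:, None, :] - foot) ** 2, axis=-1)
    best = np.argmin(dist2, axis=1)
    cum = polyline_cumlength(vertices)
    seg_len = np.sqrt(seg_len2)
    rows = np.arange(len(pts))
    s = cum[best] + t[rows, best] * seg_len[best]
    return s, np.sqrt(dist2[rows, best])


@dataclass(frozen=True)
class AxonPath:
    """Axon centerline polyline with a marked soma end.

    ``vertices_px`` are (x, y) pixel coordinates.  ``soma_at_start`` says
    whether the first vertex is the soma end; arc length is always reported
    from the soma, so anterograde movement has positive velocity regardless
    of how the polyline was digitised.
    """

    vertices_px: np.ndarray
    soma_at_start: bool = True

    def __post_init__(self):
        object.__setattr__(self, "vertices_px", _as_vertices(self.vertices_px))
        if self.length_px <= 0:
            raise ValueError("axon path has zero length")

    @property
    def oriented_vertices(self) -> np.ndarray:
        """Vertices ordered soma-first."""
        v = self.vertices_px
        return v if self.soma_at_start else v[::-1]

    @property
    def length_px(self) -> float:
        return float(polyline_cumlength(self.vertices_px)[-1])

    def length_um(self, pixel_size: float) -> float:
        return self.length_px * pixel_size

    def reversed(self) -> "AxonPath":
        """Same polyline digitised in the opposite order, marker unchanged.

        This moves the soma to the opposite physical end.
        """
        return AxonPath(self.vertices_px[::-1].copy(), self.soma_at_start)

    def with_soma_swapped(self) -> "AxonPath":
        return AxonPath(self.vertices_px.copy(), not self.soma_at_start)

    def point_at(self, s_px) -> np.ndarray:
        """(x, y) at arc length ``s_px`` measured from the soma."""
        return point_at_arclength(self.oriented_vertices, s_px)

    def tangent_at(self, s_px) -> np.ndarray:
        return tangent_at_arclength(self.oriented_vertices, s_px)

    def project(self, points):
        """Arc length from soma (px) and perpendicular distance (px)."""
        return project_onto_polyline(self.oriented_vertices, points)

    def to_frame(self) -> "np.ndarray":
        return self.vertices_px.copy()
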