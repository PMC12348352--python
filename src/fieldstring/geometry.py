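"""Angles on the torus: wrapping, shortest-arc distances, polyline projection.

Both order parameters are torsion angles, so every geometric operation lives
on the flat 2-torus [-180, 180) x [-180, 180).  Distances are Euclidean in
degrees after reducing each component to its shortest arc.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def wrap_deg(x):
    """Reduce an angle (or array of angles) in degrees to [-180, 180)."""
    return (np.asarray(x, dtype=float) + 180.0) % 360.0 - 180.0


def wrap_rad(x):
    """Reduce an angle (or array of angles) in radians to [-pi, pi)."""
    return (np.asarray(x, dtype=float) + np.pi) % (2.0 * np.pi) - np.pi


def torus_distance_deg(a, b) -> np.ndarray:
    """Shortest-arc Euclidean distance in degrees between (..., 2) arrays."""
    d = wrap_deg(np.asarray(b, dtype=float) - np.asarray(a, dtype=float))
    return np.sqrt((d * d).sum(axis=-1))


@dataclass(frozen=True)
class OPPoint:
    """A point in order-parameter space: the two torsions (phi, psi), degrees.

    Components are reduced to [-180, 180) on construction; distances between
    points are always shortest-arc on the torus.
    """

    phi: float
    psi: float

    def __post_init__(self):
        object.__setattr__(self, "phi", float(wrap_deg(self.phi)))
        object.__setattr__(self, "psi", float(wrap_deg(self.psi)))

    def as_array(self) -> np.ndarray:
        return np.array([self.phi, self.psi], dtype=float)

    def distance(self, other: "OPPoint") -> float:
        return float(torus_distance_deg(self.as_array(), other.as_array()))

    @staticmethod
    def from_array(arr) -> "OPPoint":
        arr = np.asarray(arr, dtype=float)
        return OPPoint(float(arr[0]), float(arr[1]))


def unwrap_chain(points_deg: np.ndarray) -> np.ndarray:
    """Lift an ordered (N, 2) chain of torus points to the plane.

    Each point is placed within half a period of its predecessor, so
    piecewise-linear interpolation along the chain follows shortest arcs.
    """
    pts = np.asarray(points_deg, dtype=float)
    out = pts.copy()
    for i in range(1, len(out)):
        out[i] = out[i - 1] + wrap_deg(pts[i] - out[i - 1])
    return out


def project_polyline(points_deg: np.ndarray, nodes_deg: np.ndarray,
                     nearest_idx: np.ndarray | None = None):
    """Project torus points onto a polyline of torus nodes.

    Parameters
    ----------
    points_deg : (N, 2)
    nodes_deg : (M, 2) ordered chain (consecutive nodes within half a period)
    nearest_idx : optional (N,) precomputed nearest-node indices

    Returns
    -------
    seg : (N,) index of the segment carrying the projection
    t : (N,) fractional position in [0, 1] along that segment
    d2 : (N,) squared transverse distance, deg^2
    """
    pts = np.atleast_2d(np.asarray(points_deg, dtype=float))
    nodes = np.asarray(nodes_deg, dtype=float)
    m = len(nodes)
    if nearest_idx is None:
        # brute-force nearest node on the torus
        diff = wrap_deg(pts[:, None, :] - nodes[None, :, :])
        nearest_idx = np.argmin((diff * diff).sum(axis=-1), axis=1)
    k = np.asarray(nearest_idx)

    # candidate segments around the nearest node: on curved chains the true
    # foot can sit up to two segments away from the nearest node
    candidates = [np.clip(k + off, 0, m - 2) for off in (-2, -1, 0, 1)]
    best_seg = np.empty(len(pts), dtype=int)
    best_t = np.empty(len(pts))
    best_d2 = np.full(len(pts), np.inf)
    for seg in candidates:
        p = nodes[seg]
        v = wrap_deg(nodes[seg + 1] - p)
        w = wrap_deg(pts - p)
        vv = (v * v).sum(axis=1)
        t = np.clip((w * v).sum(axis=1) / np.where(vv > 0, vv, 1.0), 0.0, 1.0)
        diff = w - t[:, None] * v
        d2 = (diff * diff).sum(axis=1)
        better = d2 < best_d2
        best_seg[better] = seg[better]
        best_t[better] = t[better]
        best_d2[better] = d2[better]
    return best_seg, best_t, best_d2
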