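"""Small 3-D geometry helpers shared by the rig and gait modules."""

from __future__ import annotations

import numpy as np

__all__ = ["unit", "ray_plane_parameter", "plane_normal"]

_PARALLEL_EPS = 1e-12


def unit(v: np.ndarray) -> np.ndarray:
    """Normalize a vector; raises on (near-)zero input."""
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n < 1e-9:
        raise ValueError("cannot normalize a zero-length vector")
    return v / n


def ray_plane_parameter(origin, direction, plane_point, plane_normal) -> float:
    """Signed parameter t with ``origin + t*direction`` on the plane.

    Returns NaN when the ray is parallel to the plane.  ``direction`` need
    not be normalized; with a unit direction t is the signed distance.
    """
    origin = np.asarray(origin, dtype=float)
    direction = np.asarray(direction, dtype=float)
    plane_point = np.asarray(plane_point, dtype=float)
    n = np.asarray(plane_normal, dtype=float)
    denom = float(n @ direction)
    if abs(denom) < _PARALLEL_EPS:
        return float("nan")
    return float(n @ (plane_point - origin)) / denom


def plane_normal(p1, p2, p3) -> np.ndarray:
    """Unit normal of the plane through three points; raises if collinear."""
    p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p1, p2, p3))
    n = np.cross(p2 - p1, p3 - p1)
    if np.linalg.norm(n) < 1e-6:
        raise ValueError("collinear points do not define a plane")
    return unit(n)
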