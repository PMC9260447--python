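"""Exact minimum enclosing sphere of a 3D point set.

Implements Welzl's randomized incremental algorithm with a convex-hull
pre-reduction (only hull vertices can lie on the optimal sphere).  The
expected running time is linear in the number of hull vertices; the hull
itself is computed by Qhull via scipy.  Degenerate inputs (collinear or
coplanar points, fewer than four points) are handled by rank-aware
circumsphere solvers.
"""

from __future__ import annotations

import sys

import numpy as np
from scipy.spatial import ConvexHull, QhullError

__all__ = ["minimum_enclosing_sphere"]

_EPS = 1e-10


def _sphere_from_support(pts: np.ndarray) -> tuple[np.ndarray, float] | None:
    """Smallest sphere with all of ``pts`` (<= 4 points) on its boundary.

    Returns None when the points are in degenerate position (the caller
    then relies on a smaller support set).
    """
    k = len(pts)
    if k == 0:
        return np.zeros(3), -1.0
    if k == 1:
        return pts[0].astype(float), 0.0
    if k == 2:
        c = (pts[0] + pts[1]) / 2.0
        return c, float(np.linalg.norm(pts[0] - c))
    # 3 or 4 points: solve 2 (p_i - p_0) . c = |p_i|^2 - |p_0|^2 restricted
    # to the affine span of the points.
    p0 = pts[0]
    d = pts[1:] - p0  # (k-1, 3)
    A = 2.0 * (d @ d.T)
    b = np.einsum("ij,ij->i", d, d)
    try:
        lam = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        return None
    c = p0 + lam @ d
    r = float(np.linalg.norm(pts[0] - c))
    return c, r


def _welzl(points: np.ndarray, rng: np.random.Generator) -> tuple[np.ndarray, float]:
    pts = points[rng.permutation(len(points))]

    def mb(n: int, support: list[np.ndarray]) -> tuple[np.ndarray, float]:
        if n == 0 or len(support) == 4:
            sph = _sphere_from_support(np.asarray(support).reshape(-1, 3))
            if sph is None:  # degenerate support; drop the oldest point
                sph = _sphere_from_support(np.asarray(support[1:]).reshape(-1, 3))
            return sph
        c, r = mb(n - 1, support)
        p = pts[n - 1]
        if np.linalg.norm(p - c) <= r * (1 + _EPS) + _EPS:
            return c, r
        return mb(n - 1, support + [p])

    old_limit = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old_limit, 4 * len(pts) + 100))
    try:
        return mb(len(pts), [])
    finally:
        sys.setrecursionlimit(old_limit)


def minimum_enclosing_sphere(points) -> tuple[np.ndarray, float]:
    """Return ``(center, radius)`` of the exact smallest enclosing sphere.

    Parameters
    ----------
    points : array-like, shape (n, 3)
        Point coordinates.  Duplicates are allowed.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("points must have shape (n, 3)")
    if len(pts) == 0:
        raise ValueError("cannot compute the enclosing sphere of zero points")
    pts = np.unique(pts, axis=0)
    if len(pts) > 16:
        try:
            hull = ConvexHull(pts)
            cand = pts[hull.vertices]
        except QhullError:
            # flat or collinear cloud: every point is a candidate
            cand = pts
    else:
        cand = pts
    # fixed RNG: the result is unique, the permutation only affects runtime
    center, radius = _welzl(cand, np.random.default_rng(0))
    # one tightening pass guards against accumulated tolerance slack
    radius = float(np.max(np.linalg.norm(pts - center, axis=1)))
    return center, radius
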