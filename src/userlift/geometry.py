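"""Planar projection and exact minimum enclosing circle.

GPS coordinates are projected into a local equirectangular frame (meters)
around a per-user origin so that Euclidean distances approximate great-circle
distances; for spans well under 50 km the error is below 0.5%.  The smallest
enclosing circle is computed exactly with Welzl's randomized incremental
algorithm.
"""
from __future__ import annotations

import warnings

import numpy as np

EARTH_RADIUS_M = 6_371_000.0

# spans beyond this make the equirectangular approximation untrustworthy
_SPAN_WARN_M = 500_000.0


def haversine_m(lat1, lon1, lat2, lon2):
    """Great-circle distance in meters between coordinate pairs (degrees)."""
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlmb = np.radians(np.asarray(lon2) - np.asarray(lon1))
    a = np.sin(dphi / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlmb / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(a))


def project_to_plane(latitude, longitude, origin):
    """Project lat/lon (degrees) to local planar x/y (meters, east/north).

    Equirectangular about ``origin = (lat0, lon0)``; exactly invertible by
    :func:`inverse_project`.
    """
    lat0, lon0 = origin
    lat = np.asarray(latitude, dtype=float)
    lon = np.asarray(longitude, dtype=float)
    x = np.radians(lon - lon0) * np.cos(np.radians(lat0)) * EARTH_RADIUS_M
    y = np.radians(lat - lat0) * EARTH_RADIUS_M
    span = 0.0
    if x.size:
        span = max(np.ptp(np.atleast_1d(x)), np.ptp(np.atleast_1d(y)))
    if span > _SPAN_WARN_M:
        warnings.warn(
            f"coordinate span {span / 1000.0:.0f} km exceeds 500 km; "
            "equirectangular projection is distorted",
            stacklevel=2,
        )
    return x, y


def inverse_project(x, y, origin):
    """Inverse of :func:`project_to_plane`; returns (latitude, longitude)."""
    lat0, lon0 = origin
    lat = lat0 + np.degrees(np.asarray(y, dtype=float) / EARTH_RADIUS_M)
    lon = lon0 + np.degrees(
        np.asarray(x, dtype=float) / (EARTH_RADIUS_M * np.cos(np.radians(lat0)))
    )
    return lat, lon


def _circle_two(p, q):
    c = (p + q) / 2.0
    return c, float(np.linalg.norm(p - c))


def _circle_three(p, q, r):
    """Circumcircle of three points; None if (near) collinear."""
    ax, ay = p
    bx, by = q
    cx, cy = r
    d = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
    if abs(d) < 1e-12:
        return None
    ux = ((ax**2 + ay**2) * (by - cy) + (bx**2 + by**2) * (cy - ay)
          + (cx**2 + cy**2) * (ay - by)) / d
    uy = ((ax**2 + ay**2) * (cx - bx) + (bx**2 + by**2) * (ax - cx)
          + (cx**2 + cy**2) * (bx - ax)) / d
    c = np.array([ux, uy])
    return c, float(np.linalg.norm(p - c))


def _contains(circle, p, eps=1e-7):
    c, r = circle
    return np.linalg.norm(p - c) <= r + eps * (1.0 + r)


def minimum_enclosing_circle(points):
    """Exact smallest circle enclosing 2-D ``points``; returns (center, radius).

    Welzl's move-to-front algorithm, expected O(n). Deterministic: the optimal
    circle is unique, and the internal shuffle is seeded.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if pts.shape[0] == 0:
        raise ValueError("minimum_enclosing_circle requires at least one point")
    if pts.shape[0] == 1:
        return pts[0].copy(), 0.0
    if pts.shape[0] > 10:
        # the optimal circle is determined by convex-hull points only
        try:
            from scipy.spatial import ConvexHull, QhullError

            pts = pts[ConvexHull(pts).vertices]
        except QhullError:
            pass  # degenerate (collinear) input: run Welzl on everything
    if pts.shape[0] == 1:
        return pts[0].copy(), 0.0
    order = np.random.default_rng(0).permutation(pts.shape[0])
    pts = pts[order]
    circle = _circle_two(pts[0], pts[1])
    for i in range(2, len(pts)):
        if not _contains(circle, pts[i]):
            circle = _mec_with_one(pts[: i + 1], pts[i])
    c, r = circle
    return c, r


def _mec_with_one(pts, p):
    circle = _circle_two(pts[0], p)
    for j in range(1, len(pts) - 1):
        if not _contains(circle, pts[j]):
            circle = _mec_with_two(pts[: j + 1], pts[j], p)
    return circle


def _mec_with_two(pts, q, p):
    circle = _circle_two(q, p)
    for k in range(len(pts) - 1):
        if not _contains(circle, pts[k]):
            c3 = _circle_three(pts[k], q, p)
            if c3 is None:
                # collinear triple: smallest circle through the farthest pair
                trio = np.array([pts[k], q, p])
                best = None
                for a in range(3):
                    for b in range(a + 1, 3):
                        cand = _circle_two(trio[a], trio[b])
                        if all(_contains(cand, t) for t in trio):
                            if best is None or cand[1] < best[1]:
                                best = cand
                c3 = best
            circle = c3
    return circle
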