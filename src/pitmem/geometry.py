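"""Segment geometry primitives shared by deposition, contact detection and clipping.

All routines are vectorised one-against-many where the deposition loop needs
them.  Lengths are unit-agnostic (the package uses nm throughout).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "clip_segment_rect",
    "clip_segment_circle",
    "point_to_segments_2d",
    "points_to_segment_2d",
    "segment_to_segments_2d",
    "segment_to_segments_3d",
]

_EPS = 1e-12


def clip_segment_rect(p0, p1, xmin, xmax, ymin, ymax):
    """Clip a 2D segment to an axis-aligned rectangle (Liang–Barsky).

    Returns (q0, q1) or None when the segment misses the rectangle.
    """
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    d = p1 - p0
    t0, t1 = 0.0, 1.0
    for delta, lo, hi, x in ((d[0], xmin, xmax, p0[0]), (d[1], ymin, ymax, p0[1])):
        if abs(delta) < _EPS:
            if x < lo or x > hi:
                return None
            continue
        ta = (lo - x) / delta
        tb = (hi - x) / delta
        if ta > tb:
            ta, tb = tb, ta
        t0 = max(t0, ta)
        t1 = min(t1, tb)
        if t0 > t1:
            return None
    q0 = p0.copy() if t0 == 0.0 else p0 + t0 * d
    q1 = p1.copy() if t1 == 1.0 else p0 + t1 * d
    return q0, q1


def clip_segment_circle(p0, p1, center, radius):
    """Clip a 2D segment to a disk. Returns (q0, q1) or None."""
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    c = np.asarray(center, dtype=float)
    if radius <= 0:
        return None
    d = p1 - p0
    f = p0 - c
    a = float(d @ d)
    if a < _EPS:  # degenerate: a point
        return (p0.copy(), p1.copy()) if f @ f <= radius**2 else None
    b = 2.0 * float(f @ d)
    cc = float(f @ f) - radius**2
    disc = b * b - 4 * a * cc
    if disc < 0:
        return None
    sq = np.sqrt(disc)
    ta = (-b - sq) / (2 * a)
    tb = (-b + sq) / (2 * a)
    t0 = max(0.0, ta)
    t1 = min(1.0, tb)
    if t0 > t1:
        return None
    q0 = p0.copy() if t0 == 0.0 else p0 + t0 * d
    q1 = p1.copy() if t1 == 1.0 else p0 + t1 * d
    return q0, q1


def point_to_segments_2d(p, b0, b1):
    """Distance from one point to N segments. b0, b1: (N, 2)."""
    p = np.asarray(p, dtype=float)
    d = b1 - b0
    den = np.einsum("ij,ij->i", d, d)
    t = np.einsum("ij,ij->i", p[None, :] - b0, d)
    t = np.divide(t, den, out=np.zeros_like(t), where=den > _EPS)
    t = np.clip(t, 0.0, 1.0)
    q = b0 + t[:, None] * d
    return np.hypot(q[:, 0] - p[0], q[:, 1] - p[1])


def points_to_segment_2d(pts, a0, a1):
    """Distance from N points to one segment. pts: (N, 2)."""
    a0 = np.asarray(a0, dtype=float)
    a1 = np.asarray(a1, dtype=float)
    d = a1 - a0
    den = float(d @ d)
    if den < _EPS:
        return np.hypot(pts[:, 0] - a0[0], pts[:, 1] - a0[1])
    t = np.clip((pts - a0) @ d / den, 0.0, 1.0)
    q = a0 + t[:, None] * d
    return np.hypot(q[:, 0] - pts[:, 0], q[:, 1] - pts[:, 1])


def _cross2(o, a, b):
    return (a[..., 0] - o[..., 0]) * (b[..., 1] - o[..., 1]) - (
        a[..., 1] - o[..., 1]
    ) * (b[..., 0] - o[..., 0])


def segment_to_segments_2d(a0, a1, b0, b1):
    """Minimum distance between one 2D segment and N others. b0, b1: (N, 2)."""
    a0 = np.asarray(a0, dtype=float)
    a1 = np.asarray(a1, dtype=float)
    b0 = np.atleast_2d(np.asarray(b0, dtype=float))
    b1 = np.atleast_2d(np.asarray(b1, dtype=float))
    d = np.minimum(
        np.minimum(point_to_segments_2d(a0, b0, b1), point_to_segments_2d(a1, b0, b1)),
        np.minimum(points_to_segment_2d(b0, a0, a1), points_to_segment_2d(b1, a0, a1)),
    )
    # proper crossings have distance zero
    aa0 = np.broadcast_to(a0, b0.shape)
    aa1 = np.broadcast_to(a1, b0.shape)
    o1 = _cross2(aa0, aa1, b0)
    o2 = _cross2(aa0, aa1, b1)
    o3 = _cross2(b0, b1, aa0)
    o4 = _cross2(b0, b1, aa1)
    cross = (o1 * o2 < 0) & (o3 * o4 < 0)
    d[cross] = 0.0
    return d


def segment_to_segments_3d(a0, a1, b0, b1):
    """Closest approach between one 3D segment and N others.

    Returns (dist, s, t, pa, pb): distances, the arc parameters on each
    segment and the closest points themselves. Clamped Ericson algorithm.
    """
    a0 = np.asarray(a0, dtype=float)
    a1 = np.asarray(a1, dtype=float)
    b0 = np.atleast_2d(np.asarray(b0, dtype=float))
    b1 = np.atleast_2d(np.asarray(b1, dtype=float))
    d1 = a1 - a0
    d2 = b1 - b0
    r = a0[None, :] - b0
    a = float(d1 @ d1)
    e = np.einsum("ij,ij->i", d2, d2)
    f = np.einsum("ij,ij->i", d2, r)
    c = d1 @ r.T
    b = d2 @ d1
    denom = a * e - b * b
    s = np.where(denom > _EPS, (b * f - c * e) / np.where(denom > _EPS, denom, 1.0), 0.0)
    s = np.clip(s, 0.0, 1.0)
    t = np.divide(b * s + f, e, out=np.zeros_like(e), where=e > _EPS)
    tc = np.clip(t, 0.0, 1.0)
    # where t was clamped, recompute s
    if a > _EPS:
        s = np.where(t != tc, np.clip((b * tc - c) / a, 0.0, 1.0), s)
    t = tc
    pa = a0[None, :] + s[:, None] * d1[None, :]
    pb = b0 + t[:, None] * d2
    dist = np.linalg.norm(pa - pb, axis=1)
    return dist, s, t, pa, pb
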