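"""Vectorised geometry for cylindrical process segments."""

from __future__ import annotations

import numpy as np

__all__ = ["segment_closest_points", "linear_kernel", "clip_segment_to_box"]

_EPS = 1e-12


def segment_closest_points(
    p1: np.ndarray, q1: np.ndarray, p2: np.ndarray, q2: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Closest points between segment pairs (p1->q1) and (p2->q2).

    All inputs are (n, 3).  Returns (c1, c2, dist) where c1/c2 are the
    closest points on each segment and dist the Euclidean distance between
    them.  Degenerate (zero-length) segments are handled as points.
    """
    p1 = np.atleast_2d(np.asarray(p1, dtype=float))
    q1 = np.atleast_2d(np.asarray(q1, dtype=float))
    p2 = np.atleast_2d(np.asarray(p2, dtype=float))
    q2 = np.atleast_2d(np.asarray(q2, dtype=float))
    d1 = q1 - p1
    d2 = q2 - p2
    r = p1 - p2
    a = np.einsum("ij,ij->i", d1, d1)
    e = np.einsum("ij,ij->i", d2, d2)
    f = np.einsum("ij,ij->i", d2, r)
    c = np.einsum("ij,ij->i", d1, r)
    b = np.einsum("ij,ij->i", d1, d2)
    denom = a * e - b * b

    s = np.where(denom > _EPS, np.clip((b * f - c * e) / np.where(denom > _EPS, denom, 1.0), 0.0, 1.0), 0.0)
    # both degenerate -> s = 0; handle e ~ 0 below
    t = np.where(e > _EPS, (b * s + f) / np.where(e > _EPS, e, 1.0), 0.0)

    # re-clamp s where t left [0, 1]
    t_low = t < 0.0
    t_high = t > 1.0
    t = np.clip(t, 0.0, 1.0)
    a_safe = np.where(a > _EPS, a, 1.0)
    s = np.where(t_low, np.clip(-c / a_safe, 0.0, 1.0), s)
    s = np.where(t_high, np.clip((b - c) / a_safe, 0.0, 1.0), s)
    s = np.where(a > _EPS, s, 0.0)

    c1 = p1 + s[:, None] * d1
    c2 = p2 + t[:, None] * d2
    dist = np.linalg.norm(c1 - c2, axis=1)
    return c1, c2, dist


def linear_kernel(x: np.ndarray, p_max: float, d1: float, d2: float) -> np.ndarray:
    """Piecewise-linear probability kernel shared by synapse placement and
    the geometric error models: ``p_max`` below ``d1``, 0 above ``d2``,
    linearly decreasing in between."""
    x = np.asarray(x, dtype=float)
    with np.errstate(invalid="ignore"):
        ramp = (d2 - x) / (d2 - d1) if d2 > d1 else np.zeros_like(x)
    p = np.where(x < d1, 1.0, np.where(x > d2, 0.0, ramp))
    return p_max * np.clip(p, 0.0, 1.0)


def clip_segment_to_box(
    start: np.ndarray, end: np.ndarray, lo: np.ndarray, hi: np.ndarray
) -> tuple[np.ndarray, np.ndarray] | None:
    """Clip one 3-D segment to an axis-aligned box (Liang-Barsky).

    Returns the clipped (start, end) or None when the segment misses the box.
    """
    start = np.asarray(start, dtype=float)
    end = np.asarray(end, dtype=float)
    d = end - start
    t0, t1 = 0.0, 1.0
    for axis in range(3):
        if abs(d[axis]) < _EPS:
            if start[axis] < lo[axis] or start[axis] > hi[axis]:
                return None
            continue
        ta = (lo[axis] - start[axis]) / d[axis]
        tb = (hi[axis] - start[axis]) / d[axis]
        if ta > tb:
            ta, tb = tb, ta
        t0 = max(t0, ta)
        t1 = min(t1, tb)
        if t0 > t1:
            return None
    return start + t0 * d, start + t1 * d
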