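"""Polyline geometry helpers and the analytic circle-crossing oracle.

The circle-crossing routine solves the quadratic for each polyline edge
against each circle and counts transversal parameter roots.  It is
deliberately independent of the sign-change counter used for intersection
profiling, so the two can cross-check each other.
"""

from __future__ import annotations

import numpy as np

__all__ = ["polyline_length", "resample_polyline", "circle_polyline_crossings"]


def polyline_length(points: np.ndarray) -> float:
    """Arclength of an ordered (n, 2) point array."""
    pts = np.asarray(points, dtype=float)
    if len(pts) < 2:
        return 0.0
    return float(np.sum(np.hypot(*np.diff(pts, axis=0).T)))


def resample_polyline(points: np.ndarray, step: float) -> np.ndarray:
    """Resample a polyline at (approximately) equal arclength steps.

    Returns points spaced ``<= step`` apart, always including both endpoints.
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < 2:
        return pts.copy()
    seg = np.hypot(*np.diff(pts, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total == 0:
        return pts[:1].copy()
    n = max(int(np.ceil(total / step)), 1)
    t = np.linspace(0.0, total, n + 1)
    x = np.interp(t, s, pts[:, 0])
    y = np.interp(t, s, pts[:, 1])
    return np.column_stack([x, y])


def circle_polyline_crossings(
    polylines: list[np.ndarray],
    center: tuple[float, float],
    radii: np.ndarray,
) -> np.ndarray:
    """Count transversal crossings of each circle by a set of polylines.

    For every edge ``p + t (q - p)``, ``t in [0, 1)``, solve
    ``|p + t (q - p) - c|^2 = r^2`` and count simple roots in the half-open
    interval (half-open so a crossing at a shared vertex is counted once).
    Tangencies (double roots) are not crossings.

    Returns an integer array, one count per radius.
    """
    cx, cy = center
    radii = np.asarray(radii, dtype=float)
    counts = np.zeros(len(radii), dtype=int)
    for pts in polylines:
        pts = np.asarray(pts, dtype=float)
        if len(pts) < 2:
            continue
        p = pts[:-1] - (cx, cy)
        d = np.diff(pts, axis=0)
        a = np.einsum("ij,ij->i", d, d)
        b = 2.0 * np.einsum("ij,ij->i", p, d)
        c0 = np.einsum("ij,ij->i", p, p)
        ok = a > 0
        for k, r in enumerate(radii):
            c = c0 - r * r
            disc = b * b - 4.0 * a * c
            trans = ok & (disc > 1e-12 * np.maximum(a, 1.0) ** 2)
            sq = np.sqrt(np.where(trans, disc, 0.0))
            with np.errstate(divide="ignore", invalid="ignore"):
                t1 = (-b - sq) / (2.0 * a)
                t2 = (-b + sq) / (2.0 * a)
            n = ((t1 >= 0.0) & (t1 < 1.0) & trans).sum()
            n += ((t2 >= 0.0) & (t2 < 1.0) & trans).sum()
            counts[k] += int(n)
    return counts
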