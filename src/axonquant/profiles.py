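"""Nerve-branch quantification along a scan direction.

Reproduces intensity-profile-based nerve scoring: at fixed intervals along
a scan axis, the full perpendicular intensity profile is extracted and the
number of distinct suprathreshold runs — each run one nerve branch — is
counted.  Also provides nerve-width measurement along a line ROI,
innervation-area measurement, and alignment of replicate profiles to a
common start.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .core import LineROI, PolygonROI, polygon_area

__all__ = [
    "BranchProfile",
    "terminal_branch_profile",
    "align_profiles",
    "nerve_width",
    "innervation_area",
]

DEFAULT_INTERVAL_UM = 30.0


@dataclass
class BranchProfile:
    """Branch counts at successive distances from a start anchor (µm)."""

    distances_um: np.ndarray
    counts: np.ndarray
    start: tuple[float, float]

    def __post_init__(self) -> None:
        self.distances_um = np.asarray(self.distances_um, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        if len(self.distances_um) != len(self.counts):
            raise ValueError("distances and counts must match in length")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        steps = np.diff(self.distances_um)
        if len(steps) and (np.any(steps <= 0) or not np.allclose(steps, steps[0])):
            raise ValueError("distances must increase by a constant step")


def _count_runs(profile: np.ndarray, threshold: float, min_run: int, merge_gap: int = 2) -> int:
    """Count suprathreshold runs, merging sub-``merge_gap`` gaps first.

    Anti-aliased line interiors can dip below threshold for a pixel; gaps
    shorter than ``merge_gap`` are bridged before run-length filtering.
    """
    above = profile > threshold
    if not above.any():
        return 0
    d = np.diff(above.astype(np.int8))
    starts = list(np.where(d == 1)[0] + 1)
    ends = list(np.where(d == -1)[0] + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(above))
    runs = []
    for s, e in zip(starts, ends):
        if runs and s - runs[-1][1] < merge_gap:
            runs[-1] = (runs[-1][0], e)
        else:
            runs.append((s, e))
    return sum(1 for s, e in runs if e - s >= min_run)


def terminal_branch_profile(
    image: np.ndarray,
    start: tuple[float, float],
    axis: tuple[float, float] = (1.0, 0.0),
    interval_um: float = DEFAULT_INTERVAL_UM,
    threshold: float | None = None,
    pixel_size_um: float = 1.0,
    min_run_px: int | None = None,
    line_width_um: float | None = None,
    max_distance_um: float | None = None,
) -> BranchProfile:
    """Count distinct nerve branches at fixed intervals along an axis.

    At each distance ``d = k * interval_um`` from ``start`` (µm coordinates)
    along ``axis``, the full perpendicular intensity profile is sampled and
    maximal runs above ``threshold`` of at least ``min_run_px`` pixels are
    counted.  The default threshold is Otsu's on the image; the default
    minimum run is ``line_width_um / pixel_size_um`` (floor 2 px).
    """
    from skimage.filters import threshold_otsu

    img = np.asarray(image, dtype=float)
    if interval_um <= 0:
        raise ValueError("interval_um must be > 0")
    h, w = img.shape
    sx, sy = start
    if not (0 <= sx <= w * pixel_size_um and 0 <= sy <= h * pixel_size_um):
        raise ValueError(f"start {start} lies outside the image")
    ax = np.asarray(axis, dtype=float)
    ax = ax / np.hypot(*ax)
    perp = np.array([-ax[1], ax[0]])
    if threshold is None:
        threshold = float(threshold_otsu(img))
    if min_run_px is None:
        if line_width_um is not None:
            min_run_px = max(int(line_width_um / pixel_size_um), 2)
        else:
            min_run_px = 2
    warned = False
    if threshold >= img.max():
        warnings.warn("threshold is at or above the image maximum", stacklevel=2)
        warned = True

    # axial extent available from the start point in the scan direction
    if max_distance_um is None:
        extent = []
        for lim, s, a in (
            (w * pixel_size_um, sx, ax[0]),
            (h * pixel_size_um, sy, ax[1]),
        ):
            if abs(a) > 1e-12:
                extent.append(((lim if a > 0 else 0.0) - s) / a)
        max_distance_um = max(min(extent) - pixel_size_um, 0.0)
    n_steps = int(np.floor(max_distance_um / interval_um))
    distances = interval_um * np.arange(1, n_steps + 1)
    # perpendicular sample offsets covering the full frame
    span = np.hypot(w, h) * pixel_size_um
    offs = np.arange(-span, span + pixel_size_um, pixel_size_um)
    counts = np.zeros(len(distances), dtype=int)
    for i, d in enumerate(distances):
        base = np.array([sx, sy]) + d * ax
        pts = base[None, :] + offs[:, None] * perp[None, :]
        cols = pts[:, 0] / pixel_size_um
        rows = pts[:, 1] / pixel_size_um
        inside = (cols >= 0) & (cols <= w - 1) & (rows >= 0) & (rows <= h - 1)
        if not inside.any():
            continue
        prof = ndi.map_coordinates(
            img, [rows[inside], cols[inside]], order=1, mode="constant"
        )
        if not warned:
            counts[i] = _count_runs(prof, threshold, min_run_px)
    return BranchProfile(distances_um=distances, counts=counts, start=(sx, sy))


def align_profiles(profiles: list[BranchProfile]) -> pd.DataFrame:
    """Align replicate profiles to their own start anchors and summarize.

    Each profile is re-indexed so distance 0 is its start; profiles are
    truncated to the shortest common extent.  Returns a distance × replicate
    table with ``mean`` and ``sem`` columns appended.
    """
    if not profiles:
        raise ValueError("need at least one profile")
    step = float(np.diff(profiles[0].distances_um)[0]) if len(
        profiles[0].distances_um
    ) > 1 else None
    rel = []
    for p in profiles:
        d = p.distances_um - p.distances_um[0]
        if step is not None and len(d) > 1 and not np.allclose(np.diff(d), step):
            raise ValueError("profiles use different sampling intervals")
        rel.append((d, p.counts))
    n_common = min(len(d) for d, _ in rel)
    dist = rel[0][0][:n_common] + (
        profiles[0].distances_um[0] - profiles[0].distances_um[0]
    )
    mat = np.stack([c[:n_common] for _, c in rel], axis=1)
    df = pd.DataFrame(
        mat,
        index=pd.Index(dist, name="distance_um"),
        columns=[f"rep{i}" for i in range(len(profiles))],
    )
    df["mean"] = mat.mean(axis=1)
    df["sem"] = (
        mat.std(axis=1, ddof=1) / np.sqrt(mat.shape[1]) if mat.shape[1] > 1 else np.nan
    )
    return df


def nerve_width(
    image: np.ndarray,
    cut: LineROI,
    threshold: float,
    pixel_size_um: float,
) -> float:
    """Nerve width along a straight cut: longest suprathreshold run × px size.

    The cut line is sampled at 1-px steps with linear interpolation; the
    result is in µm.  A cut that misses the nerve returns 0.
    """
    img = np.asarray(image, dtype=float)
    (x0, y0), (x1, y1) = cut.endpoints
    n = max(int(np.ceil(np.hypot(x1 - x0, y1 - y0))), 1)
    cols = np.linspace(x0, x1, n + 1)
    rows = np.linspace(y0, y1, n + 1)
    prof = ndi.map_coordinates(img, [rows, cols], order=1, mode="constant")
    above = prof > threshold
    if not above.any():
        return 0.0
    lab, nlab = ndi.label(above)
    sizes = ndi.sum_labels(np.ones_like(lab), lab, index=np.arange(1, nlab + 1))
    return float(sizes.max()) * pixel_size_um


def innervation_area(
    image: np.ndarray | None,
    roi: PolygonROI | None = None,
    pixel_size_um: float = 1.0,
    threshold: float | None = None,
    beyond_um: tuple[tuple[float, float], tuple[float, float]] | None = None,
) -> float:
    """Area of the innervated target field, in µm².

    With ``roi`` supplied this is the geometric area of the manually drawn
    border (the delineation analog).  Without an ROI, an automatic mode
    takes the convex hull of suprathreshold pixels, optionally restricted to
    the half-plane beyond ``beyond_um = (point, direction)`` — the terminal
    arbor past the last bifurcation.
    """
    if roi is not None:
        return polygon_area(roi, pixel_size_um)
    if image is None:
        raise ValueError("need an image for automatic mode")
    from skimage.filters import threshold_otsu

    img = np.asarray(image, dtype=float)
    if threshold is None:
        if img.max() == img.min():
            return 0.0
        threshold = float(threshold_otsu(img))
    ys, xs = np.nonzero(img > threshold)
    if len(xs) == 0:
        return 0.0
    pts = np.column_stack([xs, ys]).astype(float) * pixel_size_um
    if beyond_um is not None:
        (px, py), (dx, dy) = beyond_um
        d = np.hypot(dx, dy)
        proj = ((pts[:, 0] - px) * dx + (pts[:, 1] - py) * dy) / d
        pts = pts[proj > 0]
    if len(pts) < 3:
        return 0.0
    from scipy.spatial import ConvexHull, QhullError

    try:
        hull = ConvexHull(pts)
    except QhullError:
        return 0.0
    return float(hull.volume)  # 2-D hull: volume is the area
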