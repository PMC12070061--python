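"""Steger-style ridge detection of curvilinear structures.

Extracts bright line centerlines at sub-pixel accuracy: the image is
convolved with Gaussian derivative kernels at a scale matched to the
expected line width, pixels whose principal Hessian curvature is strongly
negative and whose sub-pixel profile maximum falls inside the pixel are
line points, and line points are linked into polylines with hysteresis on
two contrast thresholds.  Segments are split at junctions and no attempt is
made to pair continuations across a crossing — each detected segment is a
proxy for an individual axon, not a reconstructed one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .geometry import polyline_length

__all__ = ["SegmentSet", "detect_ridges", "binarize_segments", "segment_length_stats"]

_NEIGHBOR_OFFSETS = np.array(
    [(-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1)]
)
_NEIGHBOR_ANGLES = np.arctan2(_NEIGHBOR_OFFSETS[:, 0], _NEIGHBOR_OFFSETS[:, 1])


@dataclass
class SegmentSet:
    """Polyline centerlines in µm with per-segment arclengths."""

    segments: list[np.ndarray]
    image_shape: tuple[int, int]
    pixel_size_um: float
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for seg in self.segments:
            if len(seg) < 2:
                raise ValueError("every polyline needs at least 2 points")

    @property
    def lengths_um(self) -> np.ndarray:
        return np.array([polyline_length(s) for s in self.segments])

    @property
    def total_length_um(self) -> float:
        return float(self.lengths_um.sum()) if self.segments else 0.0

    def __len__(self) -> int:
        return len(self.segments)


def _contrast_to_curvature(contrast: float, width_px: float, sigma: float) -> float:
    """Hessian-eigenvalue threshold equivalent to a line-contrast threshold.

    For a bar line of full width ``w`` and height ``h`` smoothed at scale
    sigma, the second derivative magnitude at the center is
    ``2 h u exp(-u^2 / 2 sigma^2) / (sqrt(2 pi) sigma^3)`` with ``u = w/2``;
    inverting this maps user-facing contrast values onto curvature units.
    """
    u = max(width_px / 2.0, 1e-6)
    return (
        2.0
        * contrast
        * u
        * np.exp(-(u**2) / (2.0 * sigma**2))
        / (np.sqrt(2.0 * np.pi) * sigma**3)
    )


def detect_ridges(
    image: np.ndarray,
    line_width_um: float,
    low_contrast: float | None = None,
    high_contrast: float | None = None,
    pixel_size_um: float = 1.0,
    min_length_px: float = 3.0,
) -> SegmentSet:
    """Detect bright curvilinear centerlines and return them as polylines.

    Parameters
    ----------
    image
        2-D raster (background-subtracted input works best).
    line_width_um
        Expected full line width; sets the derivative scale
        ``sigma = w / (2 sqrt(3)) + 0.5`` px.
    low_contrast, high_contrast
        Hysteresis thresholds in intensity units (line height above local
        background).  Defaults: the image's 99.5 / 99.9 percentiles above
        its median.
    min_length_px
        Segments shorter than this (in pixels) are dropped as speckle.

    A blank image yields an empty set; inverted thresholds are an error.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("detect_ridges expects a 2-D raster")
    if low_contrast is None:
        low_contrast = float(np.percentile(img, 99.5) - np.median(img))
    if high_contrast is None:
        high_contrast = float(np.percentile(img, 99.9) - np.median(img))
    if low_contrast < 0 or high_contrast < low_contrast:
        raise ValueError(
            f"need high_contrast >= low_contrast >= 0, got "
            f"low={low_contrast}, high={high_contrast}"
        )
    w_px = line_width_um / pixel_size_um
    sigma = w_px / (2.0 * np.sqrt(3.0)) + 0.5

    # the truncated discrete derivative kernels have a small nonzero DC
    # response; subtract it so a constant image has exactly zero curvature
    n = 2 * int(4 * sigma + 0.5) + 9
    ones = np.ones((n, n))
    c = n // 2
    smooth0 = ndi.gaussian_filter(img, sigma, mode="nearest")

    def deriv(order):
        bias = ndi.gaussian_filter(ones, sigma, order=order, mode="nearest")[c, c]
        return ndi.gaussian_filter(img, sigma, order=order, mode="nearest") - bias * smooth0

    ry = deriv((1, 0))
    rx = deriv((0, 1))
    ryy = deriv((2, 0))
    rxy = deriv((1, 1))
    rxx = deriv((0, 2))

    # principal (most negative) eigenvalue of the Hessian and its direction
    half_tr = 0.5 * (rxx + ryy)
    root = np.sqrt(0.25 * (rxx - ryy) ** 2 + rxy**2)
    lam = half_tr - root  # bright lines: strongly negative across the line
    nx = rxy.copy()
    ny = lam - rxx
    alt = np.abs(nx) + np.abs(ny) < 1e-12
    nx[alt] = lam[alt] - ryy[alt]
    ny[alt] = rxy[alt]
    norm = np.hypot(nx, ny)
    deg = norm < 1e-12
    norm[deg] = 1.0
    nx, ny = nx / norm, ny / norm
    nx[deg], ny[deg] = 1.0, 0.0

    with np.errstate(divide="ignore", invalid="ignore"):
        t = -(rx * nx + ry * ny) / lam
    t[~np.isfinite(t)] = 1e6  # degenerate: push the point far outside
    px, py = t * nx, t * ny
    strength = -lam
    # numerical floor keeps float jitter on flat images from becoming points
    floor = 1e-9 * max(float(img.max()), 1e-30)
    t_low = max(_contrast_to_curvature(low_contrast, w_px, sigma), floor)
    t_high = max(_contrast_to_curvature(high_contrast, w_px, sigma), t_low)
    valid = (strength > t_low) & (np.abs(px) <= 0.6) & (np.abs(py) <= 0.6)

    chains = _link_line_points(valid, strength >= t_high, strength, nx, ny, px, py)

    # the smoothed ridge outlives the physical line end by about a scale
    # unit; trim chain ends below half the chain's interior amplitude (the
    # half-maximum point sits at the true endpoint)
    smooth = ndi.gaussian_filter(img, sigma, mode="nearest")
    segments = []
    for chain in chains:
        chain = _trim_chain_ends(chain, smooth)
        pts = np.asarray(chain, dtype=float) * pixel_size_um
        if len(pts) >= 2 and polyline_length(pts) >= min_length_px * pixel_size_um:
            segments.append(pts)
    return SegmentSet(
        segments=segments,
        image_shape=img.shape,
        pixel_size_um=pixel_size_um,
        params={
            "line_width_um": line_width_um,
            "sigma_px": float(sigma),
            "low_contrast": float(low_contrast),
            "high_contrast": float(high_contrast),
            "min_length_px": float(min_length_px),
        },
    )


def _trim_chain_ends(chain, smooth, frac: float = 0.5, max_trim: int = 6):
    """Drop low-amplitude points from both ends of a linked chain."""
    if len(chain) < 8:
        return chain
    vals = np.array(
        [smooth[int(round(y)), int(round(x))] for x, y in chain]
    )
    ref = frac * np.median(vals)
    a, b = 0, len(chain)
    while a < max_trim and vals[a] < ref:
        a += 1
    while b > len(chain) - max_trim and vals[b - 1] < ref:
        b -= 1
    return chain[a:b]


def _link_line_points(valid, seed_mask, strength, nx, ny, px, py):
    """Hysteresis linking of accepted line points into ordered chains.

    Starting from unvisited seeds in order of decreasing ridge strength,
    chains are extended in both tangent directions by stepping to the best
    valid neighbor among the three pixels nearest the walking direction
    (scored by sub-pixel distance plus normal-orientation mismatch).
    Returns chains of sub-pixel ``(x, y)`` pixel coordinates.
    """
    h, w = valid.shape
    visited = np.zeros_like(valid, dtype=bool)
    seeds = np.argwhere(valid & seed_mask)
    if len(seeds) == 0:
        return []
    order = np.argsort(-strength[seeds[:, 0], seeds[:, 1]])
    seeds = seeds[order]
    chains = []

    def subpix(r, c):
        return (c + px[r, c], r + py[r, c])

    def absorb_duplicates(r, c):
        # on near-45° lines two adjacent pixels can claim the same
        # sub-pixel centerline point; retire the lateral twin
        x0, y0 = subpix(r, c)
        for dr, dc in _NEIGHBOR_OFFSETS:
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and valid[rr, cc] and not visited[rr, cc]:
                x1, y1 = subpix(rr, cc)
                if np.hypot(x1 - x0, y1 - y0) < 0.75:
                    visited[rr, cc] = True

    def walk(r0, c0, direction):
        path = []
        r, c = r0, c0
        tx, ty = -ny[r, c] * direction, nx[r, c] * direction
        while True:
            ang = np.arctan2(ty, tx)
            diffs = np.abs(np.angle(np.exp(1j * (_NEIGHBOR_ANGLES - ang))))
            cand = np.argsort(diffs)[:3]
            best, best_score = None, np.inf
            x0, y0 = subpix(r, c)
            for k in cand:
                dr, dc = _NEIGHBOR_OFFSETS[k]
                rr, cc = r + dr, c + dc
                if not (0 <= rr < h and 0 <= cc < w):
                    continue
                if not valid[rr, cc] or visited[rr, cc]:
                    continue
                x1, y1 = subpix(rr, cc)
                d = np.hypot(x1 - x0, y1 - y0)
                # normal orientation mismatch, modulo pi
                dot = abs(nx[r, c] * nx[rr, cc] + ny[r, c] * ny[rr, cc])
                score = d + (1.0 - min(dot, 1.0))
                if score < best_score:
                    best, best_score = (rr, cc), score
            if best is None:
                return path
            r, c = best
            visited[r, c] = True
            absorb_duplicates(r, c)
            path.append(subpix(r, c))
            ntx, nty = -ny[r, c], nx[r, c]
            if ntx * tx + nty * ty < 0:
                ntx, nty = -ntx, -nty
            tx, ty = ntx, nty

    for r0, c0 in seeds:
        if visited[r0, c0]:
            continue
        visited[r0, c0] = True
        absorb_duplicates(r0, c0)
        fwd = walk(r0, c0, +1.0)
        bwd = walk(r0, c0, -1.0)
        chain = bwd[::-1] + [subpix(r0, c0)] + fwd
        if len(chain) >= 2:
            chains.append(chain)
    return chains


def binarize_segments(segs: SegmentSet, shape: tuple[int, int] | None = None) -> np.ndarray:
    """Rasterize all polylines into a 1-px-wide boolean mask."""
    from skimage.draw import line as _line

    if shape is None:
        shape = segs.image_shape
    out = np.zeros(shape, dtype=bool)
    for seg in segs.segments:
        pts_px = np.round(np.asarray(seg) / segs.pixel_size_um).astype(int)
        pts_px[:, 0] = np.clip(pts_px[:, 0], 0, shape[1] - 1)
        pts_px[:, 1] = np.clip(pts_px[:, 1], 0, shape[0] - 1)
        for (x0, y0), (x1, y1) in zip(pts_px[:-1], pts_px[1:]):
            rr, cc = _line(y0, x0, y1, x1)
            out[rr, cc] = True
    return out


def segment_length_stats(segs: SegmentSet) -> dict:
    """Summary statistics over per-segment arclengths.

    Returns n, mean, median, quartiles, s.e.m. (``None`` when n < 2) and the
    full length list for distribution plots.
    """
    lengths = segs.lengths_um
    n = len(lengths)
    if n == 0:
        return {
            "n": 0,
            "mean_um": None,
            "median_um": None,
            "q1_um": None,
            "q3_um": None,
            "sem_um": None,
            "lengths_um": [],
        }
    return {
        "n": n,
        "mean_um": float(lengths.mean()),
        "median_um": float(np.median(lengths)),
        "q1_um": float(np.percentile(lengths, 25)),
        "q3_um": float(np.percentile(lengths, 75)),
        "sem_um": float(lengths.std(ddof=1) / np.sqrt(n)) if n > 1 else None,
        "lengths_um": lengths.tolist(),
    }
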