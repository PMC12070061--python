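"""Intensity quantifications: region partitions, per-cell colocalization,
density-normalized counts, spot counting and gel densitometry."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .core import ImageScene, PolygonROI, polygon_mask

__all__ = [
    "RegionPartition",
    "CellColocRecord",
    "partition_signal",
    "per_cell_coloc",
    "density_normalized_count",
    "count_spots",
    "gel_band_quant",
]


@dataclass
class RegionPartition:
    """Background-subtracted signal split between a core ROI and the rest.

    ``axon_fraction``/``core_fraction`` are proportions of the total
    integrated signal (they sum to 1 exactly); ``axon_to_core_ratio`` is the
    mean intensity outside the ROI divided by the mean inside.
    """

    core_signal: float
    axon_signal: float
    core_fraction: float
    axon_fraction: float
    core_mean: float
    axon_mean: float
    axon_to_core_ratio: float


@dataclass
class CellColocRecord:
    """One cell's mean measure-channel intensity within its mask."""

    cell_id: int
    slice_index: int
    area_um2: float
    mean_measure: float


def _modal_intensity(img: np.ndarray) -> float:
    """Histogram mode of rounded intensities — a robust background level."""
    vals = np.round(img.ravel()).astype(np.int64)
    vals -= vals.min()
    return float(np.argmin(-np.bincount(vals)) + np.round(img).min())


def partition_signal(
    image: np.ndarray,
    core_roi: PolygonROI,
    background: float | None = None,
) -> RegionPartition:
    """Split background-subtracted signal between core ROI and outgrowth.

    ``background`` defaults to the modal image intensity (robust when much
    of the frame is unlabeled).  All signal quantities are clipped at 0.
    """
    img = np.asarray(image, dtype=float)
    if background is None:
        background = _modal_intensity(img)
    sig = np.clip(img - background, 0.0, None)
    inside = polygon_mask(core_roi, img.shape)
    if not inside.any() or inside.all():
        raise ValueError("core ROI must cover part, not all or none, of the image")
    core = float(sig[inside].sum())
    axon = float(sig[~inside].sum())
    total = core + axon
    if total > 0:
        axon_frac = axon / total
    else:
        axon_frac = 0.0
    core_mean = float(sig[inside].mean())
    axon_mean = float(sig[~inside].mean())
    return RegionPartition(
        core_signal=core,
        axon_signal=axon,
        core_fraction=1.0 - axon_frac,
        axon_fraction=axon_frac,
        core_mean=core_mean,
        axon_mean=axon_mean,
        axon_to_core_ratio=axon_mean / core_mean if core_mean > 0 else np.inf,
    )


def per_cell_coloc(
    scene: ImageScene,
    ch_mask: str,
    ch_measure: str,
    threshold: float | None = None,
    min_area_px: int = 20,
    min_measure_level: float | None = None,
) -> list[CellColocRecord]:
    """Mean measure-channel intensity within each mask-channel cell.

    Per z-slice, the mask channel is thresholded (Otsu by default),
    connected components of at least ``min_area_px`` pixels become cells,
    and the measure channel is averaged within each.  Slices whose measure
    channel's 99th percentile falls below ``min_measure_level`` are excluded
    as insufficiently stained.  Records from all retained slices are pooled.
    """
    from skimage.filters import threshold_otsu

    mask_arr = scene.channel(ch_mask)
    meas_arr = scene.channel(ch_measure)
    if mask_arr.ndim == 2:
        mask_arr = mask_arr[None]
        meas_arr = meas_arr[None]
    px2 = scene.pixel_size_um**2
    records: list[CellColocRecord] = []
    cell_id = 0
    for z in range(mask_arr.shape[0]):
        m = mask_arr[z].astype(float)
        b = meas_arr[z].astype(float)
        if min_measure_level is not None and np.percentile(b, 99) < min_measure_level:
            continue
        thr = threshold if threshold is not None else (
            float(threshold_otsu(m)) if m.max() > m.min() else np.inf
        )
        lab, n = ndi.label(m > thr, structure=np.ones((3, 3)))
        for i in range(1, n + 1):
            comp = lab == i
            area = int(comp.sum())
            if area < min_area_px:
                continue
            records.append(
                CellColocRecord(
                    cell_id=cell_id,
                    slice_index=z,
                    area_um2=area * px2,
                    mean_measure=float(b[comp].mean()),
                )
            )
            cell_id += 1
    if not records:
        warnings.warn("no cells found in any slice", stacklevel=2)
    return records


def density_normalized_count(count: float, reference_area_um2: float) -> float:
    """Count per µm² of reference tissue area."""
    if reference_area_um2 <= 0:
        raise ValueError("reference area must be > 0")
    return count / reference_area_um2


def count_spots(
    image: np.ndarray,
    sigma_um: float,
    threshold: float,
    pixel_size_um: float = 1.0,
) -> tuple[int, np.ndarray]:
    """Laplacian-of-Gaussian blob counting at a single scale.

    Returns the count and an ``(n, 2)`` array of ``(x, y)`` centroids in
    µm.  Spots closer than about 2 sigma merge — a resolution limit, not a
    defect.
    """
    from skimage.feature import blob_log

    img = np.asarray(image, dtype=float)
    if img.max() == img.min():
        return 0, np.empty((0, 2))
    s = sigma_um / pixel_size_um
    blobs = blob_log(
        img, min_sigma=s, max_sigma=s, num_sigma=1, threshold=threshold
    )
    if len(blobs) == 0:
        return 0, np.empty((0, 2))
    centroids = blobs[:, [1, 0]] * pixel_size_um
    return len(blobs), centroids


def gel_band_quant(
    profile: np.ndarray,
    lane_bounds: list[tuple[int, int]],
    baseline_anchors: list[tuple[int, int]] | None = None,
    control_index: int | None = None,
) -> dict:
    """Baseline-subtracted band areas from a 1-D lane profile.

    For each band, a straight baseline is interpolated through the profile
    values at its two flanking anchors (default: the band bounds
    themselves), subtracted, and the remaining area integrated by the
    trapezoidal rule and clipped at 0.  Anchor values are medians over a
    ±4-sample window so single-sample noise does not tilt the baseline.
    With ``control_index`` set, areas are also returned normalized to that
    band (the loading control).
    """
    prof = np.asarray(profile, dtype=float)
    n = len(prof)

    def anchor_level(i: int) -> float:
        lo, hi = max(i - 4, 0), min(i + 5, n)
        return float(np.median(prof[lo:hi]))
    if baseline_anchors is None:
        baseline_anchors = [tuple(b) for b in lane_bounds]
    if len(baseline_anchors) != len(lane_bounds):
        raise ValueError("need one anchor pair per band")
    areas = []
    for (lo, hi), (a1, a2) in zip(lane_bounds, baseline_anchors):
        if not (0 <= lo < hi < n and 0 <= a1 < n and 0 <= a2 < n and a1 < a2):
            raise ValueError("band bounds/anchors outside the profile")
        if not (a1 <= lo and hi <= a2):
            raise ValueError("anchors must flank their band")
        x = np.arange(lo, hi + 1, dtype=float)
        v1, v2 = anchor_level(a1), anchor_level(a2)
        base = v1 + (v2 - v1) * (x - a1) / (a2 - a1)
        resid = prof[lo : hi + 1] - base
        areas.append(max(float(np.trapezoid(resid, x)), 0.0))
    out = {"areas": areas}
    if control_index is not None:
        ctrl = areas[control_index]
        out["normalized"] = [
            a / ctrl if ctrl > 0 else np.nan for a in areas
        ]
    return out
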