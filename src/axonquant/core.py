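"""Shared data model: calibrated image scenes, ROI geometry, projections.

Conventions
-----------
Pixel coordinates are 0-based with ``x`` = column and ``y`` = row (y grows
downward, matching raster order).  Rasters are indexed ``(y, x)`` for 2-D
images and ``(z, y, x)`` for stacks.  Physical distances are derived from a
single in-plane calibration ``pixel_size_um`` (pixels assumed isotropic in
plane) and, for stacks, a slice interval ``z_step_um``; micrometre values are
never stored per pixel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage as ndi
from shapely.geometry import Polygon as _ShapelyPolygon

__all__ = [
    "ImageScene",
    "PolygonROI",
    "LineROI",
    "read_scene",
    "write_scene",
    "max_projection",
    "polygon_area",
    "polygon_mask",
    "subtract_background",
    "roi_to_json",
    "roi_from_json",
]

_SUPPORTED_DTYPES = {np.dtype("uint8"): 8, np.dtype("uint16"): 16}


@dataclass
class ImageScene:
    """A calibrated 1- or 2-channel fluorescence image or z-stack.

    Parameters
    ----------
    data
        Mapping from channel label to raster.  Each raster is ``(y, x)`` or
        ``(z, y, x)``; all channels must share one shape.
    pixel_size_um
        In-plane calibration, micrometres per pixel (> 0).
    z_step_um
        Slice interval in micrometres for stacks; ``None`` for 2-D scenes.
    bit_depth
        8 or 16; the nominal acquisition depth.
    """

    data: dict[str, np.ndarray]
    pixel_size_um: float
    z_step_um: float | None = None
    bit_depth: int = 16

    def __post_init__(self) -> None:
        if not self.data:
            raise ValueError("scene needs at least one channel")
        if self.pixel_size_um <= 0:
            raise ValueError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        shapes = {arr.shape for arr in self.data.values()}
        if len(shapes) != 1:
            raise ValueError(f"channel rasters differ in shape: {shapes}")
        (shape,) = shapes
        if len(shape) not in (2, 3):
            raise ValueError(f"rasters must be 2-D or 3-D, got shape {shape}")
        if len(shape) == 3:
            if self.z_step_um is None or self.z_step_um <= 0:
                raise ValueError("z-stacks require z_step_um > 0")
        for label, arr in self.data.items():
            if np.min(arr) < 0:
                raise ValueError(f"channel {label!r} has negative intensities")

    @property
    def channels(self) -> list[str]:
        return list(self.data)

    @property
    def shape(self) -> tuple[int, ...]:
        return next(iter(self.data.values())).shape

    @property
    def is_stack(self) -> bool:
        return len(self.shape) == 3

    def channel(self, label: str) -> np.ndarray:
        try:
            return self.data[label]
        except KeyError:
            raise KeyError(
                f"unknown channel {label!r}; scene has {self.channels}"
            ) from None


@dataclass
class PolygonROI:
    """A simple (non-self-intersecting) polygon in pixel coordinates.

    ``vertices`` is an ordered ``(n, 2)`` array of ``(x, y)`` points; the
    polygon is implicitly closed.
    """

    vertices: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValueError("vertices must be an (n, 2) array of (x, y)")
        if len(self.vertices) < 3:
            raise ValueError("a polygon needs at least 3 vertices")
        if not _ShapelyPolygon(self.vertices).is_valid:
            raise ValueError("polygon is self-intersecting or degenerate")


@dataclass
class LineROI:
    """A straight line between two distinct ``(x, y)`` pixel points."""

    endpoints: np.ndarray

    def __post_init__(self) -> None:
        self.endpoints = np.asarray(self.endpoints, dtype=float)
        if self.endpoints.shape != (2, 2):
            raise ValueError("endpoints must be a (2, 2) array of (x, y)")
        if np.allclose(self.endpoints[0], self.endpoints[1]):
            raise ValueError("line endpoints must be distinct")


def read_scene(
    path: str | Path,
    pixel_size_um: float,
    z_step_um: float | None = None,
    channel: str = "ch0",
) -> ImageScene:
    """Read a single- or multi-page greyscale TIFF as a calibrated scene.

    Multi-page files become z-stacks (``z_step_um`` then required).  The
    calibration is taken from the arguments; any metadata embedded in the
    file is ignored.  Files with more than one image series are rejected.
    """
    path = Path(path)
    if pixel_size_um <= 0:
        raise ValueError(f"pixel_size_um must be > 0, got {pixel_size_um}")
    try:
        with tifffile.TiffFile(path) as tif:
            n_series = len(tif.series)
            arr = tif.asarray() if n_series == 1 else None
    except FileNotFoundError:
        raise
    except Exception as exc:  # tifffile raises several exception types
        raise ValueError(f"could not read TIFF {path}: {exc}") from exc
    if arr is None:
        raise ValueError(
            f"{path}: multi-sample TIFF ({n_series} series) not supported"
        )
    if arr.dtype not in _SUPPORTED_DTYPES:
        raise ValueError(f"{path}: unsupported bit depth (dtype {arr.dtype})")
    bit_depth = _SUPPORTED_DTYPES[arr.dtype]
    if arr.ndim == 3 and z_step_um is None:
        raise ValueError(f"{path}: multi-page TIFF is a z-stack; pass z_step_um")
    if arr.ndim not in (2, 3):
        raise ValueError(f"{path}: expected 2-D or 3-D greyscale data, got {arr.shape}")
    return ImageScene(
        data={channel: arr},
        pixel_size_um=pixel_size_um,
        z_step_um=z_step_um if arr.ndim == 3 else None,
        bit_depth=bit_depth,
    )


def write_scene(scene: ImageScene, path: str | Path, channel: str | None = None) -> None:
    """Write one channel (default: the first) to a TIFF file."""
    label = channel if channel is not None else scene.channels[0]
    arr = scene.channel(label)
    dtype = np.uint8 if scene.bit_depth == 8 else np.uint16
    tifffile.imwrite(Path(path), arr.astype(dtype), photometric="minisblack")


def max_projection(scene: ImageScene, channel: str) -> np.ndarray:
    """Maximum-intensity z-projection of one channel.

    Returns ``out[y, x] = max_z in[z, y, x]``; a 2-D channel is returned
    unchanged (a copy).
    """
    arr = scene.channel(channel)
    if arr.ndim == 2:
        return arr.copy()
    return arr.max(axis=0)


def polygon_area(roi: PolygonROI, pixel_size_um: float) -> float:
    """Geometric (shoelace) polygon area in µm².

    The result is orientation-independent and matches the ImageJ polygon
    tool's geometric area rather than a pixel count.
    """
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be > 0")
    v = roi.vertices
    x, y = v[:, 0], v[:, 1]
    signed = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    return float(abs(signed)) * pixel_size_um**2


def polygon_mask(roi: PolygonROI, shape: tuple[int, int]) -> np.ndarray:
    """Boolean raster of pixels whose centers fall inside the polygon.

    Containment follows even-odd semantics on pixel centers.
    """
    from skimage.draw import polygon2mask

    # polygon2mask takes (row, col) = (y, x) vertex order
    return polygon2mask(shape, roi.vertices[:, ::-1])


def subtract_background(image: np.ndarray, radius: float) -> np.ndarray:
    """Subtract a morphological-opening background estimate.

    The background is the grey opening of the image with a square window of
    half-size ``radius`` pixels (separable min/max filters), a fast
    rolling-ball-style estimate: structures narrower than the window survive
    subtraction, smooth background does not.  Output is clipped at 0, so a
    constant image maps to all zeros.
    """
    if radius < 1:
        raise ValueError(f"background radius must be >= 1 pixel, got {radius}")
    img = np.asarray(image, dtype=float)
    size = 2 * int(round(radius)) + 1
    bg = ndi.maximum_filter(ndi.minimum_filter(img, size=size), size=size)
    return np.clip(img - bg, 0.0, None)


def roi_to_json(roi: PolygonROI | LineROI, pixel_size_um: float | None = None) -> str:
    """Serialize an ROI to the package's JSON record format."""
    if isinstance(roi, PolygonROI):
        rec: dict = {"type": "polygon", "vertices": roi.vertices.tolist()}
    else:
        rec = {"type": "line", "endpoints": roi.endpoints.tolist()}
    if pixel_size_um is not None:
        rec["pixel_size_um"] = pixel_size_um
    return json.dumps(rec)


def roi_from_json(text: str) -> PolygonROI | LineROI:
    rec = json.loads(text)
    if rec["type"] == "polygon":
        return PolygonROI(np.asarray(rec["vertices"]))
    if rec["type"] == "line":
        return LineROI(np.asarray(rec["endpoints"]))
    raise ValueError(f"unknown ROI type {rec.get('type')!r}")
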