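"""Grayscale echo-frame loading and region-of-interest pixel sampling.

The texture score downstream operates on the raw 8-bit intensity histogram
(0-255) of a small region of interest (ROI) placed at the myocardial-
pericardial interface of a parasternal long-axis still frame.  This module
owns the image substrate: loading DICOM/PNG/JPG frames into an 8-bit raster
and extracting the multiset of ROI pixel intensities.

Conventions
-----------
* Pixel coordinates are 0-based ``(row, col)``.
* A pixel belongs to a rectangle ROI iff its center lies in the half-open
  intervals ``[r0, r1) x [c0, c1)``.
* A pixel belongs to a polygon ROI iff its center satisfies the even-odd
  (ray crossing) rule; pixel centers sit at integer coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "GrayscaleImage",
    "RegionOfInterest",
    "IntensitySample",
    "load_grayscale",
    "extract_roi_sample",
    "DEFAULT_MIN_ROI_PIXELS",
]

#: Smallest ROI (in pixels) accepted by default; percentiles of fewer pixels
#: are too unstable to score.
DEFAULT_MIN_ROI_PIXELS = 25


@dataclass(frozen=True)
class GrayscaleImage:
    """A 2-D 8-bit intensity raster.

    Parameters
    ----------
    pixels
        2-D integer array with values in [0, 255].
    source_id
        Opaque identifier (typically the file path or subject id).
    """

    pixels: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"pixels must be 2-D, got shape {px.shape}")
        if px.size == 0:
            raise ValueError("image must contain at least one pixel")
        if px.min() < 0 or px.max() > 255:
            raise ValueError("intensities must lie in [0, 255]")
        object.__setattr__(self, "pixels", px.astype(np.uint8))

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class RegionOfInterest:
    """Rectangle or polygon ROI in pixel coordinates.

    Rectangles are stored as ``vertices = ((r0, c0), (r1, c1))`` and are
    half-open on the far edges; polygons store their vertex ring.
    """

    shape: str  # "rectangle" | "polygon"
    vertices: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.shape not in ("rectangle", "polygon"):
            raise ValueError(f"unknown ROI shape {self.shape!r}")
        verts = tuple(tuple(float(x) for x in v) for v in self.vertices)
        if self.shape == "rectangle":
            if len(verts) != 2:
                raise ValueError("rectangle ROI needs exactly 2 corner vertices")
            (r0, c0), (r1, c1) = verts
            if not (r0 < r1 and c0 < c1):
                raise ValueError("rectangle corners must satisfy r0<r1 and c0<c1")
        else:
            if len(verts) < 3:
                raise ValueError("polygon ROI needs at least 3 vertices")
        object.__setattr__(self, "vertices", verts)

    @classmethod
    def rectangle(cls, r0: float, r1: float, c0: float, c1: float) -> "RegionOfInterest":
        """Half-open rectangle over rows ``[r0, r1)`` and cols ``[c0, c1)``."""
        return cls("rectangle", ((r0, c0), (r1, c1)))

    @classmethod
    def polygon(cls, vertices: Sequence[Sequence[float]]) -> "RegionOfInterest":
        return cls("polygon", tuple(tuple(v) for v in vertices))

    def validate_within(self, image: GrayscaleImage) -> None:
        """Raise ValueError naming the offending vertex if the ROI leaves the image."""
        h, w = image.height, image.width
        for i, (r, c) in enumerate(self.vertices):
            if not (0 <= r <= h and 0 <= c <= w):
                raise ValueError(
                    f"ROI vertex {i} = ({r}, {c}) lies outside image bounds "
                    f"{h}x{w} of {image.source_id!r}"
                )


@dataclass(frozen=True)
class IntensitySample:
    """The multiset of intensities sampled from an ROI."""

    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values).ravel()
        if vals.size and (vals.min() < 0 or vals.max() > 255):
            raise ValueError("sample intensities must lie in [0, 255]")
        object.__setattr__(self, "values", vals)

    @property
    def n(self) -> int:
        return int(self.values.size)


def _luminance(arr: np.ndarray) -> np.ndarray:
    """ITU-R BT.601 luma of an RGB(A) array, rounded to integers."""
    rgb = arr[..., :3].astype(np.float64)
    y = 0.299 * rgb[..., 0] + 0.587 * rgb[..., 1] + 0.114 * rgb[..., 2]
    return np.rint(y)


def _rescale_to_8bit(arr: np.ndarray, source: str) -> np.ndarray:
    """Min-max rescale a >8-bit frame to 0-255 (ordering-preserving)."""
    arr = arr.astype(np.float64)
    lo, hi = arr.min(), arr.max()
    logger.warning(
        "rescaling >8-bit pixel data of %s from [%g, %g] to [0, 255] by min-max",
        source, lo, hi,
    )
    if hi == lo:
        return np.zeros_like(arr)
    return np.rint((arr - lo) / (hi - lo) * 255.0)


def load_grayscale(path: str | Path, frame_selector: Optional[int] = None) -> GrayscaleImage:
    """Load a DICOM, PNG, or JPG still frame as an 8-bit grayscale image.

    Multi-channel inputs are converted by luminance; DICOM pixel data wider
    than 8 bits is min-max rescaled to 0-255 (with a logged warning).  A
    multi-frame DICOM requires an explicit ``frame_selector`` -- there is no
    silent default frame.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"image file not found: {path}")
    suffix = path.suffix.lower()
    if suffix in (".dcm", ".dicom", ""):
        import pydicom

        ds = pydicom.dcmread(path)
        n_frames = int(getattr(ds, "NumberOfFrames", 1) or 1)
        arr = ds.pixel_array
        if n_frames > 1:
            if frame_selector is None:
                raise ValueError(
                    f"{path} holds {n_frames} frames; pass frame_selector "
                    "to pick the still frame explicitly"
                )
            arr = arr[frame_selector]
        if arr.ndim == 3 and arr.shape[-1] in (3, 4):
            arr = _luminance(arr)
        bits = int(getattr(ds, "BitsStored", 8) or 8)
        if bits > 8 or arr.max() > 255:
            arr = _rescale_to_8bit(arr, str(path))
    elif suffix in (".png", ".jpg", ".jpeg"):
        import imageio.v3 as iio

        arr = iio.imread(path)
        deep = arr.dtype.itemsize > 1  # e.g. 16-bit PNG
        if arr.ndim == 3:
            arr = _luminance(arr)
        if deep or (arr.size and arr.max() > 255):
            arr = _rescale_to_8bit(arr, str(path))
    else:
        raise IOError(f"unsupported image format {suffix!r} for {path}")
    return GrayscaleImage(np.asarray(arr), source_id=str(path))


def points_in_polygon(points: np.ndarray, vertices: Sequence[Sequence[float]]) -> np.ndarray:
    """Even-odd (crossing number) point-in-polygon test, vectorized.

    A point is inside iff a ray cast in the +col direction crosses the
    polygon boundary an odd number of times.
    """
    pts = np.asarray(points, dtype=np.float64)
    r, c = pts[:, 0], pts[:, 1]
    verts = np.asarray(vertices, dtype=np.float64)
    inside = np.zeros(len(pts), dtype=bool)
    n = len(verts)
    for i in range(n):
        r1, c1 = verts[i]
        r2, c2 = verts[(i + 1) % n]
        if r1 == r2:
            continue  # horizontal edge never crosses a horizontal ray
        crosses_level = (r1 > r) != (r2 > r)
        with np.errstate(divide="ignore", invalid="ignore"):
            c_int = c1 + (r - r1) / (r2 - r1) * (c2 - c1)
        inside ^= crosses_level & (c < c_int)
    return inside


def roi_pixel_mask(image: GrayscaleImage, roi: RegionOfInterest) -> np.ndarray:
    """Boolean mask of the pixels whose centers fall inside the ROI."""
    roi.validate_within(image)
    h, w = image.height, image.width
    if roi.shape == "rectangle":
        (r0, c0), (r1, c1) = roi.vertices
        rows = np.arange(h)
        cols = np.arange(w)
        mask = ((rows >= r0) & (rows < r1))[:, None] & ((cols >= c0) & (cols < c1))[None, :]
        return mask
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    centers = np.column_stack([rr.ravel(), cc.ravel()]).astype(np.float64)
    return points_in_polygon(centers, roi.vertices).reshape(h, w)


def extract_roi_sample(
    image: GrayscaleImage,
    roi: RegionOfInterest,
    min_pixels: int = DEFAULT_MIN_ROI_PIXELS,
) -> IntensitySample:
    """Sample exactly the pixels whose centers fall inside the ROI.

    Raises
    ------
    ValueError
        If the ROI exceeds the image bounds (naming the offending vertex)
        or encloses fewer than ``min_pixels`` pixel centers.
    """
    mask = roi_pixel_mask(image, roi)
    n = int(mask.sum())
    if n < min_pixels:
        raise ValueError(
            f"ROI encloses only {n} pixel(s); minimum is {min_pixels}"
        )
    return IntensitySample(image.pixels[mask])
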