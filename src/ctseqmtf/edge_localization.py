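"""Automatic placement of the edge ROI on the object/air boundary.

The scanned object (phantom or patient cross-section) sits on an air
background near -1000 HU.  Segmentation thresholds the slice, keeps the
largest 4-connected component and fills interior holes; the object centroid
is the mean of the foreground pixel coordinates.  Walking down the centroid
column from the image top, the first foreground pixel marks the top
object/air boundary, and a square ROI of (2h+1) x (2h+1) pixels (h = 20 by
default, i.e. 41 x 41) is cut out around it.  The edge is treated as locally
flat across the ROI; residual curvature of the boundary is an accepted bias.

Coordinate convention: 0-based; row = y grows downward, column = x grows to
the right; "the top of the image" is row 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .exceptions import EdgeLocalizationError, ROIBoundsError, SegmentationError
from .series_io import CTSlice

__all__ = [
    "ObjectMask",
    "EdgeCenter",
    "EdgeROI",
    "segment_object",
    "centroid",
    "find_top_edge",
    "extract_roi",
    "locate_edge_roi",
    "DEFAULT_THRESHOLD_HU",
]

#: Midpoint between air (~ -1000 HU) and tissue/PMMA (>= 0 HU).
DEFAULT_THRESHOLD_HU = -500.0


@dataclass(frozen=True)
class ObjectMask:
    """Binary mask of the segmented object (one filled connected component)."""

    mask: np.ndarray
    n_pixels: int

    def __post_init__(self) -> None:
        if self.mask.dtype != bool or self.mask.ndim != 2:
            raise ValueError("mask must be a 2-D boolean matrix")
        if self.n_pixels != int(self.mask.sum()) or self.n_pixels <= 0:
            raise ValueError("n_pixels must equal the foreground count (> 0)")


@dataclass(frozen=True)
class EdgeCenter:
    """Top-edge pixel on the centroid column, plus the centroid itself."""

    x_c: int
    y_c: int
    centroid: tuple[float, float]  # (x_a, y_b)


@dataclass(frozen=True)
class EdgeROI:
    """Square HU patch centered on the top object/air boundary."""

    patch: np.ndarray
    center: EdgeCenter
    pixel_spacing_mm: float

    def __post_init__(self) -> None:
        rows, cols = self.patch.shape
        if rows != cols or rows % 2 != 1:
            raise ValueError("patch must be square with odd side (2h+1)")

    @property
    def half_width(self) -> int:
        return self.patch.shape[0] // 2


def segment_object(ct_slice: CTSlice, threshold_hu: float = DEFAULT_THRESHOLD_HU
                   ) -> ObjectMask:
    """Threshold-binarize a slice and keep the largest filled component.

    Pixels with HU strictly above ``threshold_hu`` are foreground.  Keeping
    only the largest 4-connected component and filling interior holes guards
    against detached high-density clutter (table, clothing) and against
    low-HU inclusions inside the object.
    """
    fg = ct_slice.pixels > threshold_hu
    if not fg.any():
        raise SegmentationError(
            f"no object above threshold {threshold_hu} HU"
        )
    labels, n_components = ndimage.label(fg)  # default structure = 4-connected
    if n_components > 1:
        sizes = ndimage.sum_labels(fg, labels, index=np.arange(1, n_components + 1))
        fg = labels == (1 + int(np.argmax(sizes)))
    fg = ndimage.binary_fill_holes(fg)
    return ObjectMask(mask=fg, n_pixels=int(fg.sum()))


def centroid(mask: ObjectMask) -> tuple[float, float]:
    """Centroid (x_a, y_b) of the foreground: mean column and mean row index."""
    rows, cols = np.nonzero(mask.mask)
    return float(cols.mean()), float(rows.mean())


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def find_top_edge(mask: ObjectMask, centroid_xy: tuple[float, float]) -> EdgeCenter:
    """Intersection of the vertical centroid line with the object's top boundary.

    The centroid column x_c is the centroid x rounded half away from zero;
    y_c is the first foreground row met walking down that column from the
    image top.
    """
    x_a, y_b = centroid_xy
    x_c = _round_half_away(x_a)
    if not 0 <= x_c < mask.mask.shape[1]:
        raise EdgeLocalizationError(f"centroid column {x_c} outside the image")
    column = np.nonzero(mask.mask[:, x_c])[0]
    if column.size == 0:
        raise EdgeLocalizationError(
            f"centroid column {x_c} does not intersect the object "
            "(degenerate geometry)"
        )
    return EdgeCenter(x_c=x_c, y_c=int(column[0]), centroid=(x_a, y_b))


def extract_roi(ct_slice: CTSlice, center: EdgeCenter, half_width: int = 20
                ) -> EdgeROI:
    """Cut the (2h+1) x (2h+1) HU patch around the edge center.

    Rows y_c-h .. y_c+h and columns x_c-h .. x_c+h (0-based, inclusive).
    The patch must lie fully inside the image.
    """
    h = int(half_width)
    if h < 1:
        raise ValueError("half_width must be >= 1")
    n_rows, n_cols = ct_slice.shape
    y_c, x_c = center.y_c, center.x_c
    if y_c - h < 0 or y_c + h >= n_rows or x_c - h < 0 or x_c + h >= n_cols:
        raise ROIBoundsError(
            f"slice {ct_slice.slice_index}: ROI of half-width {h} around "
            f"(row {y_c}, col {x_c}) crosses the image border"
        )
    patch = ct_slice.pixels[y_c - h:y_c + h + 1, x_c - h:x_c + h + 1].copy()
    return EdgeROI(patch=patch, center=center,
                   pixel_spacing_mm=ct_slice.pixel_spacing_mm)


def locate_edge_roi(ct_slice: CTSlice,
                    threshold_hu: float = DEFAULT_THRESHOLD_HU,
                    half_width: int = 20) -> EdgeROI:
    """Full localization chain: segment -> centroid -> top edge -> ROI."""
    mask = segment_object(ct_slice, threshold_hu)
    center = find_top_edge(mask, centroid(mask))
    return extract_roi(ct_slice, center, half_width)
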