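"""Segment-ROI rasterization and the focal aeration measurements MPI and FHPI.

MPI (mean pixel intensity) of an ROI is the sum of its pixel values divided
by the pixel count; higher MPI means denser, less aerated tissue.  FHPI
(focal heterogeneity in pixel intensity) is the standard deviation of the
same pixel values; higher FHPI means a more uneven focal distribution of
air within the segment.  The sample (n-1) standard deviation is used,
matching the usual ROI-tool StdDev convention; the population variant is
available via ``ddof=0``.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
from matplotlib.path import Path as MplPath

from .datatypes import (
    AnnotationError,
    NormalizedRadiograph,
    SegmentMeasurement,
    SegmentROI,
    SIDES,
    SPACES,
)

__all__ = [
    "polygon_area",
    "rasterize_roi",
    "compute_mpi",
    "compute_fhpi",
    "measure_image",
]


def polygon_area(polygon: np.ndarray) -> float:
    """Signed shoelace area of a closed polygon (last edge implicit)."""
    p = np.asarray(polygon, dtype=float)
    x, y = p[:, 0], p[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))


def rasterize_roi(polygon: np.ndarray, canvas_shape: tuple[int, int]) -> np.ndarray:
    """Boolean pixel mask of a polygon on a ``(height, width)`` canvas.

    A pixel belongs to the mask iff its center (integer coordinates) lies
    inside the polygon under the even-odd rule; centers exactly on the
    boundary are included.  Degenerate (zero-area) polygons raise.
    """
    poly = np.asarray(polygon, dtype=float)
    if poly.ndim != 2 or poly.shape[1] != 2 or len(poly) < 3:
        raise AnnotationError("polygon must be an (N>=3, 2) array")
    if abs(polygon_area(poly)) == 0.0:
        raise AnnotationError("degenerate polygon: zero area")
    h, w = canvas_shape

    x0 = max(int(np.floor(poly[:, 0].min())), 0)
    x1 = min(int(np.ceil(poly[:, 0].max())), w - 1)
    y0 = max(int(np.floor(poly[:, 1].min())), 0)
    y1 = min(int(np.ceil(poly[:, 1].max())), h - 1)
    mask = np.zeros((h, w), dtype=bool)
    if x1 < x0 or y1 < y0:
        return mask

    xs = np.arange(x0, x1 + 1)
    ys = np.arange(y0, y1 + 1)
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    path = MplPath(poly)  # implicit closure; `closed=True` mis-fills
    # radius inflates or deflates depending on vertex orientation; the union
    # of both signs keeps boundary-center pixels in regardless of winding.
    eps = 1e-9
    inside = path.contains_points(pts, radius=eps) | path.contains_points(pts, radius=-eps)
    mask[y0 : y1 + 1, x0 : x1 + 1] = inside.reshape(len(ys), len(xs))
    return mask


def compute_mpi(image: np.ndarray, mask: np.ndarray) -> float:
    """Arithmetic mean of the masked pixel values."""
    vals = np.asarray(image, dtype=float)[mask]
    if vals.size == 0:
        raise ValueError("empty mask: MPI undefined")
    return float(vals.mean())


def compute_fhpi(image: np.ndarray, mask: np.ndarray, ddof: int = 1) -> float:
    """Standard deviation of the masked pixel values (sample SD by default)."""
    vals = np.asarray(image, dtype=float)[mask]
    if vals.size < 2:
        raise ValueError("FHPI needs at least 2 pixels")
    return float(vals.std(ddof=ddof))


def measure_image(
    norm: NormalizedRadiograph, ddof: int = 1, min_pixels: int = 50
) -> list[SegmentMeasurement]:
    """Measure all 12 segment ROIs of a normalized radiograph.

    Returns one :class:`SegmentMeasurement` per (side, space) in the fixed
    order right 2-7 then left 2-7.  QC-flagged ROIs (e.g. liver overlap in
    basal right segments of poorly inflated lungs) are measured anyway but
    marked ``excluded`` with the flags as the reason, so downstream
    summaries can drop them while the record count stays auditable.
    """
    ann = norm.annotations
    missing = ann.missing_rois()
    if missing:
        raise AnnotationError(f"image {norm.image_id!r}: missing segment ROI(s) {missing}")

    out: list[SegmentMeasurement] = []
    shape = norm.pixels.shape
    for side in SIDES:  # ("right", "left")
        for space in SPACES:
            roi = ann.roi(side, space)
            mask = rasterize_roi(roi.polygon, shape)
            n = int(mask.sum())
            if n < min_pixels:
                raise AnnotationError(
                    f"ROI ({side}, {space}) of {norm.image_id!r} rasterizes to "
                    f"{n} px (< {min_pixels})"
                )
            out.append(
                SegmentMeasurement(
                    image_id=norm.image_id,
                    side=side,
                    space=space,
                    mpi=compute_mpi(norm.pixels, mask),
                    fhpi=compute_fhpi(norm.pixels, mask, ddof=ddof),
                    n_pixels=n,
                    excluded=bool(roi.qc_flags),
                    reason=",".join(roi.qc_flags),
                )
            )
    return out
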