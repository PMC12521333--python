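"""Core data containers for radiograph densitometry.

Coordinate convention (shared by every module): images are row-major numpy
arrays indexed ``pixels[y, x]``; annotation coordinates are 0-based with the
origin at the top-left corner, ``x`` = column, ``y`` = row, and *integer
coordinates sit at pixel centers*.  Polygons are closed, vertices in order,
the last edge implicit.

Intensity polarity: a higher pixel value is denser tissue, i.e. a *lower*
index of aeration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

SIDES = ("right", "left")
#: Intercostal-space indices, apical (2) to basal (7).
SPACES = (2, 3, 4, 5, 6, 7)

#: QC flag set on a segment ROI that overlaps the liver shadow; such
#: measurements are excluded from summaries but kept in the output.
QC_LIVER_OVERLAP = "liver_overlap"


class AnnotationError(ValueError):
    """Raised for structurally invalid or incomplete annotations."""


@dataclass
class RawRadiograph:
    """An as-acquired grayscale radiograph.

    ``pixels`` are kept as float64 even though acquisition is integral:
    downstream normalization is multiplicative and must not quantize.
    """

    image_id: str
    pixels: np.ndarray
    bit_depth: int = 16
    metadata: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D matrix")
        if min(self.pixels.shape) < 64:
            raise ValueError("radiograph must be at least 64x64 pixels")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        ceiling = float(2**self.bit_depth - 1)
        if self.pixels.min() < 0 or self.pixels.max() > ceiling:
            raise ValueError(
                f"intensities must lie in [0, {ceiling:g}] for {self.bit_depth}-bit data"
            )


@dataclass
class ScaleBar:
    """Two endpoints of a drawn scale bar plus its physical length in mm."""

    p1: tuple[float, float]
    p2: tuple[float, float]
    mm: float = 10.0

    def __post_init__(self) -> None:
        self.p1 = (float(self.p1[0]), float(self.p1[1]))
        self.p2 = (float(self.p2[0]), float(self.p2[1]))
        if self.mm <= 0:
            raise AnnotationError("scale bar physical length must be > 0 mm")

    @property
    def pixel_length(self) -> float:
        """Euclidean endpoint separation in pixels."""
        return float(np.hypot(self.p2[0] - self.p1[0], self.p2[1] - self.p1[1]))


@dataclass
class SegmentROI:
    """One intercostal-segment region of interest.

    ``side`` is the anatomical lung side, ``space`` the intercostal-space
    index 2 (apical) through 7 (basal).
    """

    side: str
    space: int
    polygon: np.ndarray
    qc_flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.side not in SIDES:
            raise AnnotationError(f"side must be one of {SIDES}, got {self.side!r}")
        if self.space not in SPACES:
            raise AnnotationError(f"space must be in {SPACES}, got {self.space!r}")
        self.polygon = np.asarray(self.polygon, dtype=np.float64)
        if self.polygon.ndim != 2 or self.polygon.shape[1] != 2 or len(self.polygon) < 3:
            raise AnnotationError("polygon must be an (N>=3, 2) array of (x, y) vertices")
        self.qc_flags = tuple(self.qc_flags)

    @property
    def key(self) -> tuple[str, int]:
        return (self.side, self.space)


@dataclass
class AnnotationSet:
    """Per-image manual annotations: liver reference polygon, scale bar and
    the 12 segment ROIs (2 sides x intercostal spaces 2-7)."""

    image_id: str
    liver_region: np.ndarray
    scale_bar: ScaleBar
    rois: list[SegmentROI] = field(default_factory=list)
    #: Optional air (background) reference polygon for the two-point affine
    #: normalization variant; unused by the default multiplicative pipeline.
    air_region: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.liver_region = np.asarray(self.liver_region, dtype=np.float64)
        if self.air_region is not None:
            self.air_region = np.asarray(self.air_region, dtype=np.float64)

    def roi(self, side: str, space: int) -> SegmentROI:
        for r in self.rois:
            if r.key == (side, space):
                return r
        raise AnnotationError(f"missing ROI ({side}, {space}) in image {self.image_id!r}")

    def missing_rois(self) -> list[tuple[str, int]]:
        present = {r.key for r in self.rois}
        return [(s, k) for s in SIDES for k in SPACES if (s, k) not in present]

    def validate(self, image_shape: tuple[int, int] | None = None) -> None:
        """Check completeness and bounds; raise :class:`AnnotationError`."""
        missing = self.missing_rois()
        if missing:
            raise AnnotationError(
                f"image {self.image_id!r}: missing segment ROI(s) {missing}"
            )
        keys = [r.key for r in self.rois]
        if len(keys) != len(set(keys)):
            raise AnnotationError("duplicate (side, space) ROI entries")
        if image_shape is not None:
            h, w = image_shape
            for name, poly in [("liver_region", self.liver_region)] + [
                (f"roi {r.key}", r.polygon) for r in self.rois
            ]:
                if (
                    poly[:, 0].min() < -0.5
                    or poly[:, 0].max() > w - 0.5
                    or poly[:, 1].min() < -0.5
                    or poly[:, 1].max() > h - 0.5
                ):
                    raise AnnotationError(f"{name} extends outside the image bounds")

    # -- JSON serialization -------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "image_id": self.image_id,
            "liver_region": self.liver_region.tolist(),
            "scale_bar": {
                "p1": list(self.scale_bar.p1),
                "p2": list(self.scale_bar.p2),
                "mm": self.scale_bar.mm,
            },
            "rois": [
                {
                    "side": r.side,
                    "space": r.space,
                    "polygon": r.polygon.tolist(),
                    "qc": list(r.qc_flags),
                }
                for r in self.rois
            ],
        }
        if self.air_region is not None:
            d["air_region"] = self.air_region.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnnotationSet":
        sb = d["scale_bar"]
        return cls(
            image_id=d["image_id"],
            liver_region=np.asarray(d["liver_region"], dtype=float),
            scale_bar=ScaleBar(tuple(sb["p1"]), tuple(sb["p2"]), float(sb["mm"])),
            rois=[
                SegmentROI(
                    side=r["side"],
                    space=int(r["space"]),
                    polygon=np.asarray(r["polygon"], dtype=float),
                    qc_flags=tuple(r.get("qc", ())),
                )
                for r in d["rois"]
            ],
            air_region=(
                np.asarray(d["air_region"], dtype=float) if "air_region" in d else None
            ),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "AnnotationSet":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def transformed(self, scale: float = 1.0, offset: tuple[float, float] = (0.0, 0.0)) -> "AnnotationSet":
        """Return a copy with every coordinate mapped to ``p*scale + offset``."""
        ox, oy = offset

        def tpoly(p: np.ndarray) -> np.ndarray:
            return p * scale + np.array([ox, oy])

        def tpt(p: tuple[float, float]) -> tuple[float, float]:
            return (p[0] * scale + ox, p[1] * scale + oy)

        return AnnotationSet(
            image_id=self.image_id,
            liver_region=tpoly(self.liver_region),
            scale_bar=ScaleBar(tpt(self.scale_bar.p1), tpt(self.scale_bar.p2), self.scale_bar.mm),
            rois=[replace(r, polygon=tpoly(r.polygon)) for r in self.rois],
            air_region=None if self.air_region is None else tpoly(self.air_region),
        )


@dataclass
class NormalizedRadiograph:
    """An intensity- and size-normalized radiograph on the canonical canvas
    (2075 x 1170 px at 5 px/mm), with annotations in canonical coordinates."""

    image_id: str
    pixels: np.ndarray
    annotations: AnnotationSet
    reference_level: float
    size_factor: float
    px_per_mm: float = 5.0
    interpolation: str = "bilinear"


@dataclass
class SegmentMeasurement:
    """MPI/FHPI measurement of one segment ROI.

    MPI (mean pixel intensity) is the arithmetic mean over the ROI pixels;
    FHPI (focal heterogeneity in pixel intensity) is their sample standard
    deviation.  ``excluded`` marks QC-flagged segments which are retained in
    the output but dropped from summaries.
    """

    image_id: str
    side: str
    space: int
    mpi: float
    fhpi: float
    n_pixels: int
    excluded: bool = False
    reason: str = ""


def measurements_to_frame(measurements: Iterable[SegmentMeasurement]):
    """Long-format DataFrame, one row per segment measurement."""
    import pandas as pd

    rows = [
        {
            "image_id": m.image_id,
            "side": m.side,
            "space": m.space,
            "mpi": m.mpi,
            "fhpi": m.fhpi,
            "n_pixels": m.n_pixels,
            "excluded": m.excluded,
            "reason": m.reason,
        }
        for m in measurements
    ]
    return pd.DataFrame(
        rows,
        columns=["image_id", "side", "space", "mpi", "fhpi", "n_pixels", "excluded", "reason"],
    )
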