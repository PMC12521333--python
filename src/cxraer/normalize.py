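"""Two-step radiograph normalization: liver-referenced intensity scaling and
scale-bar based size normalization onto the canonical canvas.

Radiographs are acquired with varying exposure, so absolute pixel values are
not comparable between images.  The brightest pixel inside the annotated
liver region serves as a per-image reference; every pixel is rescaled
multiplicatively so that this reference lands on a common target level
(default 255.0).  A drawn scale bar of known physical length then yields a
per-image size factor mapping the image to the canonical resolution of
5 px/mm (a 10 mm bar = 50 px), after which the image is centered on the
common 2075 x 1170 px canvas.

No clipping is applied after intensity scaling: pixels brighter than the
liver reference (bone overlap) keep values above the target, because
clipping would bias downstream MPI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from .datatypes import AnnotationSet, NormalizedRadiograph, RawRadiograph, ScaleBar
from .segments import rasterize_roi

#: Canonical canvas (width, height) in pixels and canonical resolution.
CANVAS_W = 2075
CANVAS_H = 1170
PX_PER_MM = 5.0
DEFAULT_TARGET_LEVEL = 255.0


class NormalizationError(ValueError):
    pass


@dataclass
class NormalizeConfig:
    """Normalization parameters.

    target_level: common intensity assigned to the liver reference pixel.
    mode: "multiplicative" (single liver reference, the default) or
        "affine" (two-point air/liver mapping; requires an air_region
        annotation and an ``air_level`` target).
    interpolation: resampling kernel; only "bilinear" is implemented, the
        choice is recorded in the output for provenance.
    """

    target_level: float = DEFAULT_TARGET_LEVEL
    mode: str = "multiplicative"
    air_level: float = 0.0
    canvas_w: int = CANVAS_W
    canvas_h: int = CANVAS_H
    interpolation: str = "bilinear"


def find_reference_intensity(image: RawRadiograph | np.ndarray, liver_region: np.ndarray) -> float:
    """Maximum pixel intensity inside the rasterized liver polygon."""
    pixels = image.pixels if isinstance(image, RawRadiograph) else np.asarray(image, float)
    mask = rasterize_roi(liver_region, pixels.shape)
    if not mask.any():
        raise NormalizationError("liver region rasterizes to zero pixels: no reference")
    ref = float(pixels[mask].max())
    if ref <= 0:
        raise NormalizationError("liver reference intensity is zero")
    return ref


def normalize_intensity(
    pixels: np.ndarray, reference: float, target_level: float = DEFAULT_TARGET_LEVEL
) -> np.ndarray:
    """Map every pixel p to p * target_level / reference (no clipping)."""
    if reference <= 0:
        raise NormalizationError("reference intensity must be > 0")
    if target_level <= 0:
        raise NormalizationError("target level must be > 0")
    return np.asarray(pixels, dtype=np.float64) * (target_level / reference)


def normalize_intensity_affine(
    pixels: np.ndarray,
    liver_reference: float,
    air_reference: float,
    target_level: float = DEFAULT_TARGET_LEVEL,
    air_level: float = 0.0,
) -> np.ndarray:
    """Two-point variant: map air_reference -> air_level and
    liver_reference -> target_level linearly."""
    if liver_reference <= air_reference:
        raise NormalizationError("liver reference must exceed air reference")
    scale = (target_level - air_level) / (liver_reference - air_reference)
    return (np.asarray(pixels, dtype=np.float64) - air_reference) * scale + air_level


def compute_size_factor(scale_bar: ScaleBar, px_per_mm: float = PX_PER_MM) -> float:
    """Spatial scale factor mapping the drawn bar to canonical resolution.

    factor = (physical length in mm * px_per_mm) / drawn pixel length, so a
    10 mm bar drawn 100 px long gives 0.5 and ends up 50 px after scaling.
    """
    d = scale_bar.pixel_length
    if d <= 0:
        raise NormalizationError("scale bar endpoints coincide")
    return (scale_bar.mm * px_per_mm) / d


def resample(pixels: np.ndarray, factor: float) -> np.ndarray:
    """Bilinear resampling by a uniform scale factor.

    Output dimensions are round(input * factor); a factor of exactly 1
    returns the input unchanged.  Annotation coordinates are transformed
    separately (multiplied by the same factor) by the caller.
    """
    if not (0.05 < factor < 20):
        raise NormalizationError(f"size factor {factor:g} outside the supported range (0.05, 20)")
    pixels = np.asarray(pixels, dtype=np.float64)
    if factor == 1.0:
        return pixels.copy()
    h, w = pixels.shape
    out_h = int(round(h * factor))
    out_w = int(round(w * factor))
    if out_h < 8 or out_w < 8:
        raise NormalizationError(f"resampled image {out_w}x{out_h} is smaller than 8x8")
    return resize(
        pixels,
        (out_h, out_w),
        order=1,  # bilinear
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
        clip=False,
    )


def place_on_canvas(
    pixels: np.ndarray, canvas_w: int = CANVAS_W, canvas_h: int = CANVAS_H
) -> tuple[np.ndarray, tuple[int, int]]:
    """Center the image on the canonical canvas (zero padding).

    Returns (canvas, (x_offset, y_offset)).
    """
    h, w = pixels.shape
    if w > canvas_w or h > canvas_h:
        raise NormalizationError(
            f"image {w}x{h} exceeds the {canvas_w}x{canvas_h} canvas; "
            "check the scale-bar annotation"
        )
    ox = (canvas_w - w) // 2
    oy = (canvas_h - h) // 2
    canvas = np.zeros((canvas_h, canvas_w), dtype=np.float64)
    canvas[oy : oy + h, ox : ox + w] = pixels
    return canvas, (ox, oy)


def normalize_radiograph(
    raw: RawRadiograph,
    annotations: AnnotationSet,
    config: NormalizeConfig | None = None,
) -> NormalizedRadiograph:
    """Full normalization: intensity scaling, size scaling, canvas placement.

    Annotation coordinates are carried through: multiplied by the size
    factor, then shifted by the canvas offset.  Raises with the missing
    (side, space) named if any of the 12 segment ROIs is absent.
    """
    cfg = config or NormalizeConfig()
    annotations.validate(image_shape=raw.pixels.shape)

    reference = find_reference_intensity(raw, annotations.liver_region)
    if cfg.mode == "affine":
        if annotations.air_region is None:
            raise NormalizationError("affine mode requires an air_region annotation")
        air_ref = float(raw.pixels[rasterize_roi(annotations.air_region, raw.pixels.shape)].min())
        scaled = normalize_intensity_affine(
            raw.pixels, reference, air_ref, cfg.target_level, cfg.air_level
        )
    elif cfg.mode == "multiplicative":
        scaled = normalize_intensity(raw.pixels, reference, cfg.target_level)
    else:
        raise NormalizationError(f"unknown normalization mode {cfg.mode!r}")

    factor = compute_size_factor(annotations.scale_bar)
    resampled = resample(scaled, factor)
    canvas, (ox, oy) = place_on_canvas(resampled, cfg.canvas_w, cfg.canvas_h)
    ann = annotations.transformed(scale=factor, offset=(ox, oy))

    return NormalizedRadiograph(
        image_id=raw.image_id,
        pixels=canvas,
        annotations=ann,
        reference_level=cfg.target_level,
        size_factor=factor,
        px_per_mm=PX_PER_MM,
        interpolation=cfg.interpolation,
    )
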