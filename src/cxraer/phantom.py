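"""Synthetic neonatal chest-radiograph phantoms with ground truth.

The study's patient radiographs are not public, so validation rests on
phantoms that reproduce the *statistical* structure the analysis assumes,
not radiographic realism:

* two vertically elongated elliptical lung fields on a darker thoracic
  background;
* a linear apico-basal mean-intensity gradient per side,
  ``mean(side, k) = base_side + slope_side * k`` for intercostal-space
  index k = 2 (apical) .. 7 (basal) — negative slopes make basal segments
  darker, i.e. better aerated;
* a left-minus-right intensity offset;
* per-segment Gaussian speckle whose SD is the FHPI ground truth;
* a bright uniform liver plateau (the strict intensity maximum, as the
  normalization reference requires);
* a drawn scale bar of known physical length; and
* a per-image exposure gain multiplying every pixel, which the
  liver-referenced normalization must cancel.

Default intercepts/slopes are the surfactant-treated cohort's fitted lines
(right: -1.99x + 117.79, left: -1.75x + 123.71); the pre-surfactant group
defaults are set so per-lung mean MPI matches the reported 98.6 (right) /
102 (left).

Speckle is truncated at 0 and at the bit-depth ceiling; spec validation
keeps every segment mean at least 5 SD away from both bounds so the
truncation bias is negligible (< 3e-6 of a SD).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .datatypes import (
    AnnotationSet,
    RawRadiograph,
    ScaleBar,
    SegmentROI,
    SIDES,
    SPACES,
)

__all__ = [
    "LungEllipse",
    "PhantomSpec",
    "PhantomTruth",
    "PhantomBundle",
    "GroupSpec",
    "CohortSpec",
    "CohortResult",
    "generate_phantom",
    "generate_cohort",
]

MEAN_SPACE_INDEX = float(np.mean(SPACES))  # 4.5


class PhantomSpecError(ValueError):
    pass


@dataclass(frozen=True)
class LungEllipse:
    """Axis-aligned ellipse (pixel coordinates of the raw canvas)."""

    cx: float
    cy: float
    a: float  # horizontal semi-axis
    b: float  # vertical semi-axis

    def half_width(self, y: float) -> float:
        t = 1.0 - ((y - self.cy) / self.b) ** 2
        return self.a * math.sqrt(t) if t > 0 else 0.0


def _default_geometry(w: int, h: int) -> dict[str, LungEllipse]:
    # anatomical right lung appears on the image left (AP view)
    a = 0.1375 * w
    b = 0.3833 * h
    cy = 0.50 * h
    return {
        "right": LungEllipse(cx=0.29 * w, cy=cy, a=a, b=b),
        "left": LungEllipse(cx=0.71 * w, cy=cy, a=a, b=b),
    }


@dataclass
class PhantomSpec:
    """Generative parameters of one phantom radiograph.

    Intensities are on the pre-gain scale; with the default liver intensity
    equal to the normalization target (255), truth values are unchanged by
    the full normalization pipeline.
    """

    canvas_w: int = 800
    canvas_h: int = 600
    base_intensity_right: float = 117.79
    base_intensity_left: float = 123.71
    slope_right: float = -1.99
    slope_left: float = -1.75
    #: per-segment speckle SD, keyed by (side, space); the FHPI ground truth
    speckle_sd: dict[tuple[str, int], float] = field(
        default_factory=lambda: {(s, k): 8.0 for s in SIDES for k in SPACES}
    )
    liver_intensity: float = 255.0
    background_intensity: float = 60.0
    scale_bar_mm: float = 10.0
    scale_bar_px: float = 50.0
    scale_bar_intensity: float = 220.0
    exposure_gain: float = 1.0
    bit_depth: int = 16
    lung_geometry: dict[str, LungEllipse] | None = None
    #: fraction of the vertical semi-axis covered by the 6 segment bands
    band_extent: float = 0.9
    roi_margin_px: float = 3.0

    def geometry(self) -> dict[str, LungEllipse]:
        return self.lung_geometry or _default_geometry(self.canvas_w, self.canvas_h)

    def uniform_speckle(self, sd: float) -> "PhantomSpec":
        return replace(self, speckle_sd={(s, k): sd for s in SIDES for k in SPACES})

    def expected_mean(self, side: str, space: int) -> float:
        base = self.base_intensity_right if side == "right" else self.base_intensity_left
        slope = self.slope_right if side == "right" else self.slope_left
        return base + slope * space

    def validate(self) -> None:
        if self.exposure_gain <= 0:
            raise PhantomSpecError("exposure_gain must be > 0")
        keys = {(s, k) for s in SIDES for k in SPACES}
        if set(self.speckle_sd) != keys:
            raise PhantomSpecError("speckle_sd must have exactly 12 (side, space) entries")
        if any(v < 0 for v in self.speckle_sd.values()):
            raise PhantomSpecError("speckle SDs must be non-negative")
        ceiling = float(2**self.bit_depth - 1)
        max_lung = max(self.expected_mean(s, k) for s, k in keys)
        if self.liver_intensity <= max_lung:
            raise PhantomSpecError(
                "liver_intensity must strictly exceed every expected lung intensity "
                "(it is the normalization reference)"
            )
        if self.liver_intensity <= self.background_intensity:
            raise PhantomSpecError("liver_intensity must exceed the background")
        if self.liver_intensity <= self.scale_bar_intensity:
            raise PhantomSpecError("liver_intensity must exceed the scale bar")
        if self.liver_intensity * self.exposure_gain > ceiling:
            raise PhantomSpecError("liver plateau exceeds the bit-depth ceiling after gain")
        for (s, k), sd in self.speckle_sd.items():
            mean = self.expected_mean(s, k)
            if mean - 5 * sd < 0:
                raise PhantomSpecError(f"segment ({s},{k}) mean is within 5 SD of 0")
            if (mean + 5 * sd) * self.exposure_gain > ceiling:
                raise PhantomSpecError(f"segment ({s},{k}) mean is within 5 SD of the ceiling")


@dataclass
class PhantomTruth:
    """Injected noiseless parameters, on the post-normalization scale."""

    segment_means: dict[tuple[str, int], float]
    slopes: dict[str, float]
    intercepts: dict[str, float]
    speckle_sd: dict[tuple[str, int], float]
    #: left-minus-right difference of per-lung mean MPI
    lr_offset: float

    @property
    def mean_mpi(self) -> float:
        return float(np.mean(list(self.segment_means.values())))


@dataclass
class PhantomBundle:
    image: RawRadiograph
    annotations: AnnotationSet
    truth: PhantomTruth


def _segment_bands(spec: PhantomSpec, ell: LungEllipse) -> list[tuple[float, float]]:
    """Vertical extent [y0, y1) of each of the 6 bands, space 2 (top) first."""
    top = ell.cy - spec.band_extent * ell.b
    bot = ell.cy + spec.band_extent * ell.b
    edges = np.linspace(top, bot, len(SPACES) + 1)
    return [(float(edges[i]), float(edges[i + 1])) for i in range(len(SPACES))]


def _roi_polygon(spec: PhantomSpec, ell: LungEllipse, y0: float, y1: float) -> np.ndarray:
    """Inset rectangle inside the ellipse band: 0.75 px vertical gap keeps
    every rasterized pixel center strictly within its own band."""
    yy0, yy1 = y0 + 0.75, y1 - 0.75
    hw = min(ell.half_width(yy0), ell.half_width(yy1)) - spec.roi_margin_px
    if hw < 4.0:
        raise PhantomSpecError("lung geometry too small for segment ROIs")
    return np.array(
        [
            [ell.cx - hw, yy0],
            [ell.cx + hw, yy0],
            [ell.cx + hw, yy1],
            [ell.cx - hw, yy1],
        ]
    )


def _liver_rect(spec: PhantomSpec) -> tuple[int, int, int, int]:
    """Drawn liver plateau (x0, x1, y0, y1), inclusive pixel bounds."""
    w, h = spec.canvas_w, spec.canvas_h
    return (int(0.12 * w), int(0.45 * w), int(0.90 * h), int(0.965 * h))


def generate_phantom(
    spec: PhantomSpec, seed: int, image_id: str | None = None
) -> PhantomBundle:
    """Render one phantom radiograph with annotations and ground truth.

    Identical (spec, seed) pairs yield bit-identical bundles.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    w, h = spec.canvas_w, spec.canvas_h
    image_id = image_id or f"phantom-{seed:08d}"

    img = np.full((h, w), spec.background_intensity, dtype=np.float64)
    yy, xx = np.mgrid[0:h, 0:w]

    geometry = spec.geometry()
    rois: list[SegmentROI] = []
    for side in SIDES:
        ell = geometry[side]
        inside = ((xx - ell.cx) / ell.a) ** 2 + ((yy - ell.cy) / ell.b) ** 2 <= 1.0
        bands = _segment_bands(spec, ell)
        top, bot = bands[0][0], bands[-1][1]
        band_h = (bot - top) / len(SPACES)
        # band index per pixel row; apex/base rows outside the band range
        # take the nearest band's parameters
        band_idx = np.clip(np.floor((yy - top) / band_h), 0, len(SPACES) - 1).astype(int)
        for i, space in enumerate(SPACES):
            sel = inside & (band_idx == i)
            mean = spec.expected_mean(side, space)
            sd = spec.speckle_sd[(side, space)]
            vals = mean + (rng.standard_normal(int(sel.sum())) * sd if sd > 0 else 0.0)
            img[sel] = vals
            rois.append(
                SegmentROI(side=side, space=space, polygon=_roi_polygon(spec, ell, *bands[i]))
            )

    # bright liver plateau: the strict pre-gain maximum
    lx0, lx1, ly0, ly1 = _liver_rect(spec)
    img[ly0 : ly1 + 1, lx0 : lx1 + 1] = spec.liver_intensity
    liver_poly = np.array(
        [[lx0 + 2, ly0 + 2], [lx1 - 2, ly0 + 2], [lx1 - 2, ly1 - 2], [lx0 + 2, ly1 - 2]],
        dtype=float,
    )

    # scale bar near the bottom edge
    bx0 = int(0.06 * w)
    bx1 = bx0 + spec.scale_bar_px
    if bx1 > w - 2:
        raise PhantomSpecError("scale bar does not fit on the canvas")
    by = int(0.982 * h)
    img[by - 1 : by + 2, bx0 : int(math.ceil(bx1)) + 1] = spec.scale_bar_intensity
    scale_bar = ScaleBar(p1=(float(bx0), float(by)), p2=(float(bx1), float(by)), mm=spec.scale_bar_mm)

    ceiling = float(2**spec.bit_depth - 1)
    img = np.clip(img * spec.exposure_gain, 0.0, ceiling)

    annotations = AnnotationSet(
        image_id=image_id, liver_region=liver_poly, scale_bar=scale_bar, rois=rois
    )
    annotations.validate(image_shape=img.shape)
    _reject_overlapping_rois(rois)

    truth = PhantomTruth(
        segment_means={(s, k): spec.expected_mean(s, k) for s in SIDES for k in SPACES},
        slopes={"right": spec.slope_right, "left": spec.slope_left},
        intercepts={"right": spec.base_intensity_right, "left": spec.base_intensity_left},
        speckle_sd=dict(spec.speckle_sd),
        lr_offset=(
            (spec.base_intensity_left + spec.slope_left * MEAN_SPACE_INDEX)
            - (spec.base_intensity_right + spec.slope_right * MEAN_SPACE_INDEX)
        ),
    )
    raw = RawRadiograph(image_id=image_id, pixels=img, bit_depth=spec.bit_depth,
                        metadata=f"phantom seed={seed} gain={spec.exposure_gain:g}")
    return PhantomBundle(image=raw, annotations=annotations, truth=truth)


def _reject_overlapping_rois(rois: list[SegmentROI]) -> None:
    boxes = []
    for r in rois:
        p = r.polygon
        boxes.append((r.key, p[:, 0].min(), p[:, 0].max(), p[:, 1].min(), p[:, 1].max()))
    for i in range(len(boxes)):
        for j in range(i + 1, len(boxes)):
            k1, ax0, ax1, ay0, ay1 = boxes[i]
            k2, bx0, bx1, by0, by1 = boxes[j]
            if ax0 < bx1 and bx0 < ax1 and ay0 < by1 and by0 < ay1:
                raise PhantomSpecError(f"overlapping ROI polygons {k1} and {k2}")


# ---------------------------------------------------------------------------
# Cohort generation


@dataclass
class GroupSpec:
    """Population parameters of one study arm."""

    n: int
    base_intensity_right: float
    base_intensity_left: float
    slope_right: float
    slope_left: float


def _default_groups() -> dict[str, GroupSpec]:
    # STG lines from the fitted apico-basal regressions; PSG intercepts
    # chosen so per-lung mean MPI is 98.6 (right) / 102 (left).
    return {
        "STG": GroupSpec(n=52, base_intensity_right=117.79, base_intensity_left=123.71,
                         slope_right=-1.99, slope_left=-1.75),
        "PSG": GroupSpec(n=8, base_intensity_right=98.6 + 2.0 * MEAN_SPACE_INDEX,
                         base_intensity_left=102.0 + 1.75 * MEAN_SPACE_INDEX,
                         slope_right=-2.0, slope_left=-1.75),
    }


@dataclass
class CohortSpec:
    """Generative model of a simulated cohort.

    Patient i of a group draws an intercept shift delta_i ~ N(0,
    intercept_sd) applied to both lung sides (so the left-right offset is
    preserved), a per-image exposure gain, and clinical covariates:

    * MAP_day1 = map_alpha + map_beta * (patient mean MPI) + N(0, map_resid_sd)
      (cmH2O); days 3 and 7 add an independent drift.
    * grade = 1 + #{thresholds below mean MPI}, with probability
      grade_noise moved one step (monotone step mapping plus label noise).
    * FiO2 clipped-normal in [0.21, 1.0]; VT (mL/kg) with a small per-day
      shift; respiratory severity score RSS = MAP * FiO2.
    """

    groups: dict[str, GroupSpec] = field(default_factory=_default_groups)
    intercept_sd: float = 15.0
    speckle_sd: float = 8.0
    gain_range: tuple[float, float] = (0.7, 1.4)
    scale_bar_px: float = 50.0
    phantom_template: PhantomSpec = field(default_factory=PhantomSpec)
    map_alpha: float = -12.3
    map_beta: float = 0.2
    map_resid_sd: float = 5.4827
    map_day_drift_sd: float = 1.0
    fio2_mean: float = 0.30
    fio2_sd: float = 0.08
    vt_mean: float = 5.0
    vt_sd: float = 0.8
    vt_day_shift: dict[int, float] = field(default_factory=lambda: {1: 0.0, 3: -0.3, 7: -0.5})
    grade_thresholds: tuple[float, ...] = (97.0, 109.0, 121.0)
    grade_noise: float = 0.10
    days: tuple[int, ...] = (1, 3, 7)
    master_seed: int = 0

    def validate(self) -> None:
        if any(g.n < 2 for g in self.groups.values()):
            raise PhantomSpecError("each group needs n >= 2 patients")
        if self.intercept_sd < 0 or self.map_resid_sd < 0 or self.speckle_sd < 0:
            raise PhantomSpecError("SD parameters must be non-negative")
        if list(self.grade_thresholds) != sorted(set(self.grade_thresholds)):
            raise PhantomSpecError("grade thresholds must be strictly increasing")

    # -- the MPI-MAP correlation implied by the model ----------------------

    @property
    def true_map_correlation(self) -> float:
        """Population Pearson correlation between patient mean MPI and MAP
        within one group (between-patient spread = intercept_sd)."""
        s = self.map_beta * self.intercept_sd
        denom = math.hypot(s, self.map_resid_sd)
        return s / denom if denom > 0 else float("nan")

    @staticmethod
    def residual_sd_for_correlation(r: float, beta: float, intercept_sd: float) -> float:
        """Residual SD giving population correlation r for the MAP model."""
        if not 0 < abs(r) <= 1:
            raise ValueError("r must be in (0, 1]")
        return abs(beta) * intercept_sd * math.sqrt(1.0 / r**2 - 1.0)

    @classmethod
    def from_yaml(cls, path) -> "CohortSpec":
        import yaml

        d = yaml.safe_load(open(path)) or {}
        groups = d.pop("groups", None)
        spec = cls(**{k: v for k, v in d.items() if k in cls.__dataclass_fields__})
        if groups:
            spec.groups = {name: GroupSpec(**g) for name, g in groups.items()}
        if "vt_day_shift" in d:
            spec.vt_day_shift = {int(k): float(v) for k, v in d["vt_day_shift"].items()}
        return spec


@dataclass
class CohortResult:
    bundles: list[PhantomBundle] | None
    clinical: pd.DataFrame
    patients: pd.DataFrame
    truths: dict[str, PhantomTruth]


def generate_cohort(cohort: CohortSpec, render_images: bool = True) -> CohortResult:
    """Simulate a cohort: one phantom per patient plus clinical covariates.

    Per-patient seeds derive deterministically from the master seed
    (numpy SeedSequence spawning), so identical master seeds regenerate
    bit-identical cohorts and patients are mutually independent.  With
    ``render_images=False`` only covariates and ground truth are produced
    (no pixel rendering) — sufficient for covariate-model studies such as
    correlation-recovery simulations.
    """
    cohort.validate()
    master = np.random.SeedSequence(cohort.master_seed)
    n_total = sum(g.n for g in cohort.groups.values())
    children = master.spawn(n_total + 1)
    cov_rng = np.random.default_rng(children[0])

    bundles: list[PhantomBundle] | None = [] if render_images else None
    clinical_rows = []
    patient_rows = []
    truths: dict[str, PhantomTruth] = {}

    idx = 0
    for group_name, g in cohort.groups.items():
        for j in range(g.n):
            idx += 1
            pid = f"{group_name}-{j + 1:03d}"
            image_seed = int(children[idx].generate_state(1)[0] % (2**31))
            delta = cov_rng.normal(0.0, cohort.intercept_sd)
            gain = cov_rng.uniform(*cohort.gain_range)

            spec = replace(
                cohort.phantom_template,
                base_intensity_right=g.base_intensity_right + delta,
                base_intensity_left=g.base_intensity_left + delta,
                slope_right=g.slope_right,
                slope_left=g.slope_left,
                exposure_gain=gain,
                scale_bar_px=cohort.scale_bar_px,
            ).uniform_speckle(cohort.speckle_sd)

            if render_images:
                bundle = generate_phantom(spec, seed=image_seed, image_id=pid)
                truth = bundle.truth
                bundles.append(bundle)
            else:
                truth = PhantomTruth(
                    segment_means={(s, k): spec.expected_mean(s, k) for s in SIDES for k in SPACES},
                    slopes={"right": spec.slope_right, "left": spec.slope_left},
                    intercepts={"right": spec.base_intensity_right,
                                "left": spec.base_intensity_left},
                    speckle_sd=dict(spec.speckle_sd),
                    lr_offset=(
                        (spec.base_intensity_left + spec.slope_left * MEAN_SPACE_INDEX)
                        - (spec.base_intensity_right + spec.slope_right * MEAN_SPACE_INDEX)
                    ),
                )
            truths[pid] = truth

            x = truth.mean_mpi
            map1 = cohort.map_alpha + cohort.map_beta * x + cov_rng.normal(0, cohort.map_resid_sd)
            grade = 1 + int(np.searchsorted(cohort.grade_thresholds, x))
            if cov_rng.random() < cohort.grade_noise:
                grade += int(cov_rng.choice([-1, 1]))
            grade = int(np.clip(grade, 1, 4))

            patient_rows.append(
                {
                    "patient_id": pid,
                    "group": group_name,
                    "image_seed": image_seed,
                    "exposure_gain": gain,
                    "true_mean_mpi": x,
                    "grade": grade,
                }
            )
            for day in cohort.days:
                mday = map1 if day == 1 else map1 + cov_rng.normal(0, cohort.map_day_drift_sd)
                fio2 = float(np.clip(cov_rng.normal(cohort.fio2_mean, cohort.fio2_sd), 0.21, 1.0))
                vt = cov_rng.normal(cohort.vt_mean + cohort.vt_day_shift.get(day, 0.0), cohort.vt_sd)
                clinical_rows.append(
                    {
                        "patient_id": pid,
                        "group": group_name,
                        "day": day,
                        "map_cmh2o": mday,
                        "fio2": fio2,
                        "vt_ml_kg": vt,
                        "rss": mday * fio2,
                        "grade": grade,
                    }
                )

    return CohortResult(
        bundles=bundles,
        clinical=pd.DataFrame(clinical_rows),
        patients=pd.DataFrame(patient_rows),
        truths=truths,
    )
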