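# Methods

## Model and assumptions

The pipeline treats a frontal chest radiograph as a 2-D intensity field in
which attenuation is monotone in tissue density: brighter pixels are
denser, less aerated lung.  Three assumptions carry the whole analysis:

1. **A multiplicative exposure model.** Differences in exposure act as a
   positive gain on all pixels of an image.  Dividing by a per-image
   reference — the brightest pixel of the annotated liver, an organ dense
   enough to sit above any aerated lung — removes the gain exactly.  The
   normalization is multiplicative only; an optional two-point air/liver
   affine variant exists behind `NormalizeConfig(mode="affine")` but is
   off by default, since a single-reference scaling is the standard
   procedure and an offset term would change MPI's interpretation.
2. **A linear spatial calibration.** A drawn scale bar of known physical
   length determines a single isotropic factor mapping the image to
   5 px/mm; all images live on a common 2075 × 1170 px canvas afterwards.
3. **Segment homogeneity of interest.** Within an intercostal-segment
   ROI, the mean (MPI) measures regional density and the sample SD (FHPI)
   focal heterogeneity.  Across the six segments of a lung field, the SD
   of MPIs (STDV-MPI) and of FHPIs (STDV-FHPI) summarize between-segment
   heterogeneity, and the regression of segment means on space index 2–7
   summarizes the apico-basal gradient.

## Parameters that matter

| parameter | default | units | rationale |
|---|---|---|---|
| `target_level` | 255.0 | intensity | common liver level after normalization; the 8-bit ceiling is a natural display scale and keeps phantom truth on its generative scale |
| px/mm | 5.0 | px/mm | canonical resolution: a 10 mm bar spans 50 px |
| canvas | 2075 × 1170 | px | common frame for all normalized images |
| interpolation | bilinear | — | standard choice of ROI tooling; recorded in provenance output |
| FHPI ddof | 1 | — | sample SD, matching the usual ROI-tool StdDev; vs. population SD the difference is < 0.1 % at typical ROI sizes and the choice is configurable |
| min ROI area | 50 | px | guards against meaningless SDs on sliver ROIs |

Phantom and cohort defaults encode the study conditions being emulated:
apico-basal lines −1.99·k + 117.79 (right) and −1.75·k + 123.71 (left)
for the surfactant-treated arm; the pre-surfactant arm's intercepts are
set so per-lung mean MPI is 98.6 (right) / 102 (left); between-patient
intercept SD 15 (near the reported per-lung SDs of 13–17); segment
speckle SD 8; liver plateau 255; exposure gain uniform on (0.7, 1.4);
group sizes 52 + 8 (60 images, 720 segment records).  The day-1 MAP model
is `MAP = α + β·meanMPI + ε` with β = 0.2 cmH₂O per intensity unit and
residual SD 5.48, giving a population MPI–MAP correlation of 0.48; the
radiological grade is a monotone step map of mean MPI (thresholds 97,
109, 121) with 10 % label noise.

## What the phantom emulates — and what it does not

Emulated: the statistical structure the analysis relies on (linear
gradients, left–right offset, segment speckle as FHPI truth, a strictly
maximal liver plateau, scale-bar geometry, exposure gain).  Not emulated:
ribs, mediastinum and other anatomy, scatter, detector noise correlation,
ROI placement error, or between-day radiograph series.  Passing recovery
tests therefore shows the *pipeline* is correct and unbiased under its
own model; it does not validate the biological claims on real
radiographs, where ROI placement and anatomical overlap dominate the
error budget.

Speckle is Gaussian truncated at 0 and the bit-depth ceiling; spec
validation requires every segment mean to sit ≥ 5 SD from both bounds, so
the truncation bias is below 3 × 10⁻⁶ of a SD and ignored.

## Numerical choices

* **Rasterization** uses the pixel-center even-odd rule (integer
  coordinates at pixel centers, boundary centers included), implemented on
  matplotlib's path machinery and verified against a brute-force
  ray-crossing oracle on random polygons.
* **Resampling** is bilinear with output size `round(dims × factor)`;
  a factor of exactly 1 short-circuits to identity, which makes
  normalization idempotent and keeps canonical-scale phantoms free of
  interpolation smoothing.  Annotation coordinates are scaled by the exact
  factor (not the per-axis effective scale), so the transformed bar length
  is exact and ROI alignment error stays below half a pixel — inside every
  stated tolerance.
* **Canvas placement** is centered with zero padding; MPI/FHPI are
  translation invariant, so this only affects visualization.
* **No clipping** after intensity normalization: bone-overlap pixels
  brighter than the liver keep values above the target rather than biasing
  MPI downward.
* **Raw phantoms are float64 in memory**; the PNG writer rounds to
  integers, so disk round-trips add ≤ 0.5 intensity units of quantization.
  Exactness claims (gain invariance to 1e−9) refer to the in-memory path.
* **Degenerate inputs** are reported, not silenced: zero-variance
  correlation inputs yield an undefined-r report rather than r = 0;
  all-tied Friedman tables yield statistic 0 and p = 1; zero-variance
  Welch inputs yield a flagged degenerate p ∈ {0, 1}.
* **Friedman** is computed in the tie-corrected general form
  `(k−1)·S/D` (mid-ranks), which supports k = 2 and matches scipy for
  k ≥ 3 without ties.  **Conover's post hoc** uses the rank-LSD standard
  error `√(2n(A−B)/((n−1)(k−1)))` with A = Σr²ᵢⱼ and B = (1/n)ΣR²ⱼ —
  A − B is the error SS of the two-way rank layout — on (n−1)(k−1) df.
* **Fisher's exact** two-sided p is the summed-probabilities rule (all
  same-margin tables no more probable than observed), the common software
  convention; doubling the one-sided p is the main alternative and gives
  different values on asymmetric margins.

## Validation problem sizes

Replicate-heavy checks run on a reduced 320 × 240 raw canvas (segment
areas of several hundred pixels, MPI sampling noise ≈ σ/20), a size chosen
so 200-replicate gradient-recovery and 500-replicate correlation-recovery
studies complete in a couple of minutes while leaving every tolerance
dominated by the statistic under test, not rendering resolution.
Correlation recovery uses the generator's covariate-only mode (no pixel
rendering): the measured mean-MPI differs from truth by ~0.1 intensity
units against a 15-unit between-patient SD, so rendering 26 000 images
would change r̂ in the third decimal at most.  Full-resolution,
full-cohort rendering (60 images, 800 × 600 raw, canonical canvas) is
exercised separately by the bookkeeping checks and the acceptance script.

## Known limitations

* The Conover post hoc is a t-approximation to a very discrete
  permutation null at small n: against the exact studentized within-block
  permutation distribution (k = 3), pairwise p can deviate by ~0.1–0.15
  in mid-range p for n ≤ 5.  In the decision-relevant tail (p ≤ 0.1,
  n ≥ 4) agreement is within 0.05.  For confirmatory use at tiny n, use
  the permutation p directly.
* Left-vs-right comparisons default to the heteroscedastic unpaired t
  (the battery's stated method) although the sides are paired within
  patients; a paired alternative is trivial to run from the summaries
  table and will generally be more powerful.
* ROIs are supplied, never detected; annotation quality is an input, not
  something the pipeline can check beyond structural validation.
* No multiplicity adjustment is applied across the report's distinct
  hypotheses; Bonferroni/Conover adjustments apply only within
  repeated-measures families.
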