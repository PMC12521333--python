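# cxraer — chest-radiograph lung-aeration densitometry

`cxraer` quantifies focal lung aeration in neonatal chest radiographs
(CXRs), the way it is done when studying respiratory distress syndrome
(RDS) in extremely preterm infants: plain frontal CXRs are the routine
bedside imaging, but their absolute pixel values are not comparable across
exposures, and visual grading compresses the whole lung into one ordinal
score.  The package implements the full quantitative alternative —
reference-region normalization, segment-wise densitometry, heterogeneity
indices, apico-basal gradient fits and the accompanying statistics — as a
tested, scriptable pipeline, together with a synthetic phantom generator
that provides ground truth for end-to-end validation.  It is aimed at
neonatology and pediatric-radiology researchers who have (or simulate)
annotated radiographs and want reproducible aeration metrics.

## Method

1. **Intensity normalization.** The brightest pixel inside a manually
   annotated liver polygon is the per-image reference; every pixel `p` is
   rescaled to `p · T / ref` so the liver lands on a common target level
   `T` (default 255).  Purely multiplicative, no clipping — exposure gain
   cancels exactly.
2. **Size normalization.** A drawn scale bar of known physical length
   gives the factor `(mm · 5 px/mm) / drawn px`, mapping every image to
   5 px/mm (10 mm = 50 px) by bilinear resampling, then centering it on
   the common 2075 × 1170 px canvas.
3. **Segment measurements.** Twelve ROIs — intercostal spaces 2 (apical)
   to 7 (basal) on each lung — are rasterized by a pixel-center even-odd
   rule.  Per ROI:
   * **MPI** (mean pixel intensity) = Σpᵢ / n: higher MPI = denser,
     less aerated tissue;
   * **FHPI** (focal heterogeneity in pixel intensity) = sample SD of the
     same pixels: higher FHPI = more uneven focal air distribution.
   QC-flagged ROIs (e.g. liver overlap of the right basal segment) stay in
   the output but are excluded from summaries.
4. **Summaries and gradients.** Per lung field: mean MPI/FHPI and their
   between-segment SDs (STDV-MPI, STDV-FHPI).  Per group and side, the
   cell means over spaces 2–7 are fit by OLS (`mean = a + b·space`), with
   Pearson r tested via `t = r√((n−2)/(1−r²))`.
5. **Statistics.** Welch's heteroscedastic two-sided t-test, Fisher's
   exact test (summed-probabilities two-sided rule), Pearson correlation,
   one-way repeated-measures ANOVA with Bonferroni post hoc, and the
   Friedman test with Conover's (1999) all-pairs post hoc.

The phantom generator renders elliptical lung fields whose segment means
follow injected linear apico-basal gradients, per-segment Gaussian speckle
(the FHPI ground truth), a bright liver plateau, a drawn scale bar, and a
per-image exposure gain, plus cohort-level clinical covariates (MAP, FiO₂,
VT, respiratory severity score, radiological grade 1–4) generated from the
patient's true mean MPI with known effect sizes.

## Worked example

The numbered drivers under `analysis/` run a demo cohort (12
surfactant-treated + 6 pre-surfactant patients):

```bash
python analysis/01_simulate.py
python analysis/02_normalize_measure.py
python analysis/03_summaries_gradients.py
python analysis/04_group_stats.py
```

which prints, among other lines:

```
measured 216 segments from 18 images (0 excluded by QC)
MPI range: 77.7 - 146.3 | FHPI mean: 8.0

apico-basal gradient fits (MPI):
group  side  slope  intercept    r   p
  STG right -1.991    115.193 -1.0 0.0
  STG  left -1.753    121.101 -1.0 0.0

28 comparisons, 3 with p < 0.05:
                    comparison    method  statistic      p
         mean MPI vs MAP day 1 pearson_r     0.6980 0.0013
         mean MPI vs RSS day 1 pearson_r     0.6267 0.0054
mean MPI vs radiological grade pearson_r     0.9460 0.0000
```

Reading: 18 patients × 12 segments = 216 records; the fitted apico-basal
slopes (−1.99 right, −1.75 left) recover the injected gradients — denser
apices, better-aerated bases; the group cell means average patient-level
speckle away, so r rounds to −1.0 and p to 0 at three decimals.  Mean MPI
correlates with day-1 mean airway pressure and with the simulated
radiological grade, as built into the cohort model; at n = 18 the weaker
covariate links (FiO₂, VT) stay below significance.

The same pipeline is available as a CLI (`cxraer simulate|normalize|
measure|summarize|stats|run`, each with `--seed`, `--config`, `--out`).

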