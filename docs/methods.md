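# Methods

## The quantification problem

PAS stains glycogen magenta/purple; hematoxylin counterstains nuclei blue.
On bright-field images of stained smears, classic color deconvolution with
fixed stain vectors fails because the stain tones drift slightly from
sample to sample. The approach implemented here sidesteps fixed vectors:
after flat-field correction, every stained pixel is reduced to its hue
angle, and the two dyes appear as two peaks in the hue histogram — a
dominant hematoxylin peak near 250° and a PAS subpeak on its high-hue
shoulder near 270°. Deconvolving the histogram into two skewed peaks and
taking the PAS peak's share of the total area gives a per-cell glycogen
index in [0, 1] that is robust to overall tone shifts (a shift moves both
peaks; the area ratio survives).

## Flat-field correction

`I_c = 255 (I_s − I_d)/(I_b − I_d)` per pixel per channel, where `I_b` and
`I_d` are open- and blocked-light-path calibration frames. Computation is
floating point with clipping to [0, 255]; pixels with a degenerate
denominator (`I_b − I_d ≤ ε`, no illumination information) are set to 0 and
a warning is raised if they exceed 1% of the image. Corrected images stay
at float precision internally and are rounded half-away-from-zero only when
written to disk. On the synthetic generator's own forward model
(noise-free), correction recovers the ideal scene to within one intensity
unit; the residual is the 8-bit quantization of the specimen divided by the
local gain (≤ 0.5/0.6 ≈ 0.83).

## Hue histograms

Hexcone RGB→HSB conversion (hue in degrees, S and B in [0, 1]; achromatic
pixels get H = 0 and are removed by the saturation filter). Per cell,
pixels with S ≥ 0.08 and B ∈ [0.05, 0.98] enter a uniform hue histogram;
excluded-pixel counts are recorded so that counts + excluded = cell pixels.
Hue circularity is ignored: both stains sit far from the 0°/360° seam.

**Bin width (default 2°).** 8-bit RGB sources produce *discrete* hue values
with spacing 60/(max−min) degrees — about 0.71° for typical stained pixels
here. One-degree bins alias this comb into the histogram and bias the peak
fit by about −0.02 in the PAS index on noise-free images; two-degree bins
average over at least two discrete hue levels and remove the effect (bias
≈ −0.006, and noise or vignetting dithers it away entirely). The bin width
remains a parameter for sources where the comb is finer.

## Two-component EMG deconvolution

Each peak is an exponentially modified Gaussian with area `A`, location
`μ`, Gaussian width `σ`, and exponential tail `τ` toward larger hue —
the right-skew matches the observed shape of smear hue histograms:

```
f(x) = 1/(2τ) · exp((μ−x)/τ + σ²/(2τ²)) · erfc((μ−x)/(√2σ) + σ/(√2τ))
```

evaluated through `erfcx` so neither flank overflows, with the pure
exponential tail form used when the scaled argument is very negative.

The 8-parameter two-component model is fitted to the per-cell histogram by
bounded trust-region least squares (`scipy.optimize.least_squares`, TRF):

- **Bin integrals, not point densities.** Model counts are Simpson-rule
  integrals of the density over each bin. The midpoint rule's O(bw²)
  curvature error (~1% of peak counts at 2° bins) is otherwise absorbed by
  a spurious second component.
- **Counting-statistics weights.** Residuals are
  `(model − counts)/√(model + 1)` (Pearson weighting): a bin count's
  variance is its expectation. On identical rendered cells this halves the
  area-split error relative to unweighted least squares.
- **Bounds.** `μ_hema ∈ [230, 262]`, `μ_PAS ∈ [265, 300]`,
  `σ, τ ∈ [0.5, 30]`, areas in [0, 2×total]. The PAS location floor sits
  3° above the 262° midpoint between the nominal peaks: if it is allowed
  down to 262°, the second component can degenerate into a shoulder
  correction of the hematoxylin peak — on pure single-peak data it absorbs
  ~3% of the area for a χ² improvement that is insignificant for four
  extra parameters, biasing the index.
- **Initialization and restarts.** μ = (250, 270), σ = (6, 6), τ = (5, 5),
  area split 80/20 of histogram mass; up to 5 seeded jittered restarts if
  the optimizer fails. Components are sorted by μ; the fit requires ≥ 8
  nonzero bins.
- **Fallback.** If no restart converges, the index falls back to the
  fraction of counts at hue ≥ 262° and the cell is flagged
  (`fallback_used`), never dropped.

The PAS index is `A_PAS/(A_PAS + A_hema)`, clipped to [0, 1]. Fitting is
per cell by default because individual cells are the unit of comparison; a
pooled per-image mode exists.

**Accuracy.** On synthetic cells of ~1.9×10⁴ pixels the estimator is
approximately unbiased with a per-cell standard error of ~0.005–0.010
(tests assert max |error| ≤ 0.02 noise-free and ≤ 0.05 at default sensor
noise, against the realized per-cell dye fraction). The error is dominated
by the area-split ambiguity of two overlapping peaks, so it shrinks
roughly as (pixels)^−1/2: small cells give noisier indices.

## Segmentation

Thresholding on the corrected image (S ≥ 0.08, B ∈ [0.05, 0.98]) followed
by 8-connected labeling, minimum area 50 px. This suffices for
well-separated smear cells; any externally produced label mask can be
supplied instead and is used verbatim.

## Cohort statistics

- Activities are normalized per subject by a reference enzyme tied to a
  normal glycolytic state (pyruvate kinase "high affinity" in the bundled
  table); z-standardization uses the sample (n−1) SD. t statistics and r²
  are invariant under these affine maps, which the tests verify.
- One-sided two-sample t-tests come in pooled (equal-variance,
  df = n₁+n₂−2) and Welch (Welch–Satterthwaite df) variants, from raw
  vectors or from published mean/SD/n summaries; both variants are
  first-class because published small-cohort tables rarely state which was
  used. On the bundled table the pooled form reproduces the published
  p-value row; the glucose-uptake comparison is reproduced by Welch on
  summary statistics.
- Group definitions (young < 40, old > 50 by default) and the exclusion of
  a median-aged subject are explicit parameters, not automatic rules.
- The bundled activity table carries a known label shift: the published
  per-enzyme r² and p lists match recomputation only when each named
  enzyme maps to the column one position to its left. The package
  therefore keys printed-number checks to column *positions* and documents
  the discrepancy rather than guessing the intended labels.
- `compare_pas_indices` reports old/young fold change, a one-sided test
  (old greater), and the share of old cells above the young maximum.

## Lineage priming and enrichment

Counts are scaled per cell to the median library size and log1p-transformed
(a deliberately minimal normalization, adequate for marker-mean scoring and
invariant to per-cell depth). A cell's myeloid and lymphoid scores are mean
log-normalized expression over the respective marker sets; the call is
myeloid-primed if the myeloid score exceeds the lymphoid score by more than
a margin (default 0.25 on the log scale), mirrored for lymphoid, else
unprimed. The margin is a declared choice — no published threshold exists.

A proliferation gene is "detected" in a lineage × age group when it has a
count ≥ 1 in ≥ 25% of the group's cells (robust to dropout; both knobs are
parameters). Lineage enrichment uses the one-sided ("greater") Fisher exact
test on the detected/undetected table; the p-value is exactly the
hypergeometric tail, which the tests confirm against brute-force
enumeration over all 2×2 tables with margins ≤ 12. Young-vs-old shifts are
tested per lineage on per-cell gene-set scores with the one-sided t-test.

## Synthetic data: what it emulates, and what it does not

`render_scene` draws elliptical cells on a near-white background
(S < 0.05). Each cell pixel carries the PAS dye with probability `p_pas`,
else hematoxylin; the dye hue is drawn from a right-skewed EMG-shaped
distribution (Gaussian core σ = 4°, exponential tail τ = 3° toward larger
hue, truncated at 3σ/5τ) at fixed S = 0.55, B = 0.60 — matching the skewed
peak shape real smear histograms show, which is the reason the
deconvolution stage fits EMGs in the first place. Illumination is a
per-channel 2nd-order polynomial gain in [0.6, 0.95]; the upper bound keeps
`dark + gain × 255 ≤ 255` so the open light path never saturates the 8-bit
sensor (as in practice, where exposure is set to avoid clipping the
background). Sensor noise is additive Gaussian (sd 2 intensity units)
before round-half-away-from-zero quantization. Calibration frames are
returned as noise-free floats, modeling the average of many frames; on disk
they are 8-bit. The ground truth records both `p_pas` and the *realized*
dye fraction of each cell's rendered pixels; recovery is judged against the
realized fraction because the binomial pixel-assignment noise
(≈ √(p(1−p)/n_px)) is part of the scene, not of the measurement.

Default grid cells have semi-axes (88, 70) px ≈ 1.9×10⁴ pixels — a
10–12 μm progenitor cell at 100× oil immersion with ~0.07 μm pixels. The
cohort generator draws per-cell `p_pas` from Beta distributions with young
mean 0.08 (SD 0.02) and old mean 0.28 (SD 0.10): a 3.5× fold change with
greater old-group heterogeneity, 3 + 3 subjects and 24 cells per subject by
default. With these tight young dispersions nearly all old cells exceed the
young range; emulating the published ~25% overlap statistic would require
far larger young heterogeneity than a six-subject fold-recovery design
tolerates, so that statistic is reported but not calibrated.

The activity generator is `activity = (baseline + slope·age) ·
exp(N(0, 0.3²))` per enzyme. The expression generator plants two donors per
age group, equal myeloid/lymphoid cells, 10× marker elevation in a cell's
own lineage, and a 3× proliferation-gene boost confined to old
myeloid-primed cells; proliferation genes get a sparse baseline (mean 0.2
vs 2.0 for other genes) so the detection rule separates the boosted group
instead of saturating. Counts are negative binomial (dispersion 0.5;
Poisson at 0).

What passing these tests does *not* show: performance on real smears with
overlapping or out-of-focus cells, debris, stain-intensity gradients within
a cell, drifted peak positions outside the fit bounds, or hue distributions
departing strongly from the EMG shape. The generator models none of these;
it validates the numerical chain, not the histology.

## Problem sizes

The default test and acceptance runs use 8-cell scenes, a 6-subject × 24-cell
cohort, 10⁵-sample histograms for fit-recovery checks, the exhaustive
margin ≤ 12 Fisher sweep (5 550 tables), and 100 expression replicates of
200 genes × 240 cells — sizes at which every check is stable and the whole
suite completes in a few minutes on one CPU.

## Known limitations

- The PAS index is a *relative* area ratio, not an absolute glycogen mass;
  cross-study comparability depends on consistent staining and imaging.
- Per-cell index error grows for small or weakly stained cells (few
  filtered pixels); the fit needs ≳ 10⁴ pixels for ~0.01 precision.
- The two-component model assumes exactly two dyes; additional chromogens
  would need a different model (explicitly out of scope).
- Fisher enrichment aggregates detection over age groups within a lineage;
  donors are not modeled as random effects anywhere (the published designs
  are too small for that).
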