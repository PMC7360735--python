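# pasquant

Semi-quantitative scoring of cellular glycogen content from bright-field
images of periodic acid–Schiff (PAS) + hematoxylin stained cell smears,
with the accompanying small-cohort statistics and a marker-based
lineage-priming analysis for CD34+ hematopoietic progenitor cells.

## Who this is for

Labs that stain smears with PAS (glycogen → magenta/purple) over a
hematoxylin counterstain (nuclei → blue) and want a per-cell, per-subject
glycogen index from ordinary 8-bit RGB microscope images — without color
deconvolution, which fails on these stains because peak tones drift from
sample to sample.

## The method

1. **Flat-field correction.** With an open-light-path frame `I_b` and a
   blocked-path frame `I_d`, each specimen image `I_s` is corrected as

   `I_c = 255 · (I_s − I_d) / (I_b − I_d)`

   removing inhomogeneous illumination and sensor-response variation.
2. **HSB conversion.** Corrected RGB pixels are mapped to
   hue (0–360°) / saturation / brightness. Hematoxylin appears as a "blue"
   hue peak near 250°, PAS as a "purple" subpeak near 270°.
3. **Hue-histogram deconvolution.** For each segmented (or user-masked)
   cell, the hue histogram of its stained pixels is fitted with a sum of two
   exponentially modified Gaussians (EMG: Gaussian core, exponential tail
   toward larger hue) by bounded trust-region least squares with
   counting-statistics weights.
4. **PAS index.** The glycogen score of a cell is the fitted PAS peak area
   over the total fitted area, `A_PAS / (A_PAS + A_hema)` ∈ [0, 1].

Around this core the package provides

- `pasquant.cohort` — reference-enzyme normalization, z-standardization,
  age-trend r², one-sided two-sample t-tests (pooled and Welch, from raw
  data or published summary statistics), young/old group summaries, and the
  glycogen-index fold-change comparison;
- `pasquant.lineage` — myeloid/lymphoid priming calls from marker-gene
  scores on a gene × cell count matrix, proliferation-gene detection counts,
  and one-sided Fisher exact enrichment;
- `pasquant.synthetic` — generators for smear images (with calibration
  frames, label masks, and per-cell ground truth), enzyme-activity tables,
  and count matrices with planted effects, so the whole pipeline is testable
  end to end;
- `pasquant.datasets` — a bundled published nine-subject table of
  glycolytic enzyme activities (ages 19–71) and glucose-uptake subset
  summaries used by the worked examples and tests.

## Worked example

Render a small synthetic cohort, quantify it, and compare age groups:

```python
import numpy as np
from pasquant import synthetic, images, cohort

spec = synthetic.CohortSpec(seed=1)        # 3 young vs 3 old subjects,
young, old = [], []                        # old mean PAS fraction 3.5x young
for subject in synthetic.simulate_cohort_images(spec):
    r = subject.render
    cells = images.quantify_image_set(r.specimen, r.calibration, mask=r.mask)
    (young if subject.group == "young" else old).extend(
        m.pas_index for m in cells
    )
res = cohort.compare_pas_indices(young, old)
print(f"fold change {res.fold_change:.2f}, one-sided p = {res.t.p:.2e}")
```

prints

```
fold change 3.61, one-sided p = 7.62e-37
```

i.e. the pipeline recovers the planted 3.5× old/young glycogen ratio and the
old group is significantly higher. The bundled enzyme table reproduces the
published statistics it ships with:

```python
from pasquant import datasets, cohort
table = datasets.load_enzyme_activities()
cols = datasets.activity_columns(table)
s = cohort.summarize_groups(table, exclude_ids=["307"])
print(round(s.old_mean[cols[2]], 2))       # 16.64 (old-group mean, column 3)
print(round(cohort.age_trend_r2(table, cols[1]).r2, 2))   # 0.43
```

(Column positions matter here: the published per-enzyme labels are shifted
by one column relative to the table, see `pasquant.datasets` docstring.)

The same operations are scriptable via the CLI:

```sh
pasquant simulate images --config cohort.yaml --seed 1 --out imgs/
pasquant quantify --image imgs/young_1_specimen.png \
    --bright imgs/young_1_bright.png --dark imgs/young_1_dark.png \
    --mask imgs/young_1_mask.png --out cells.csv
pasquant stats activities --exclude 307
pasquant lineage --matrix counts.csv --annotations cells.csv --markers markers/ --out enrich/
```

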