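# octex

Layer-resolved **texture and thickness analysis of volumetric retinal OCT**
for longitudinal two-group studies, with a synthetic speckle-phantom
generator that makes every stage testable without external data.

`octex` is aimed at preclinical imaging groups who follow retinal
neurodegeneration over time — for example in rodent models of diabetic
retinopathy — and want quantitative, reproducible readouts from segmented
OCT volumes before overt structural damage appears.

## What it computes

Given a stack of B-scans (a 3-D intensity volume indexed
`(bscan, ascan, depth)`) and seven segmented interface surfaces delimiting
six retinal structures (NFL-GCL, IPL, INL, OPL, ONL, IS/OS):

1. **Mean-value fundus (MVF) projection.** For each layer, a 2-D en-face
   image whose pixel `(b, a)` is the mean of the A-scan samples between the
   layer's two bounding interfaces — the half-open integer interval
   `[⌈upper⌉, ⌈lower⌉)`, so adjacent layers partition each A-scan exactly.
2. **GLCM texture features.** Each MVF image is quantized to
   `N_g` grey levels (min–max, `N_g = 64` by default), co-occurrence counts
   are accumulated over four unit-distance directions under the validity
   mask, symmetrized and normalized into `p(i, j)`, and 20 Haralick-type
   features are computed (angular second moment, contrast, correlation,
   sum of squares, inverse difference moment, sum average/variance/entropy,
   entropy, difference variance/entropy, IMCI, IMCII, autocorrelation,
   maximum probability, cluster prominence/shade, INN, IDN, dissimilarity).
   Entropies are in bits; degenerate conventions are documented in
   `docs/methods.md`.
3. **Thickness.** Per-layer thickness maps `depths[k+1] − depths[k]`
   (sub-pixel boundaries allowed), the total retina as interface 6 minus
   interface 0 (identically the sum of the six layers), per-eye means and
   percent of baseline `100 · v_t / v_0`.
4. **Longitudinal statistics.** At each follow-up week, texture endpoints
   are compared between groups by ANCOVA with the week-0 value as a
   quantitative covariate (`value_t ~ group + value_0`, OLS); thickness
   endpoints (as percent of baseline) by Student's t-test or Mann–Whitney U,
   gated per group by Shapiro–Wilk; significance at α = 0.05, two-sided,
   uncorrected by default (Benjamini–Hochberg behind a flag).

The synthetic module generates layered speckle phantoms (unit-mean gamma
speckle with configurable contrast and lateral correlation length) and full
control/T2D cohorts imaged at weeks 0/4/8/12, with per-(layer, week)
thinning and texture effects and exact ground-truth boundaries.

## Worked example

Simulate a small cohort in which the photoreceptor segments (IS/OS) thin to
~89% of baseline and develop finer speckle texture at weeks 8 and 12, then
run the full analysis:

```python
from octex import CohortConfig, LayerEffect
from octex.synthetic import iter_cohort
from octex.pipeline import analyze_scans, default_endpoints
from octex.stats import run_full_comparison

effects = {("IS/OS", 8):  LayerEffect(thickness_factor=0.89, corr_length_factor=0.7),
           ("IS/OS", 12): LayerEffect(thickness_factor=0.91, corr_length_factor=0.7)}
cfg = CohortConfig(n_control=8, n_t2d=8, effects=effects, seed=1)
features, thickness, cohort, _ = analyze_scans(iter_cohort(cfg))
results = run_full_comparison(cohort, default_endpoints())
```

Filtering the significant IS/OS results gives (output of the snippet above):

```
                  measure layer  week   test  estimate      p
              correlation IS/OS     8 ancova   -0.1370 0.0000
              correlation IS/OS    12 ancova   -0.1329 0.0000
inverse_difference_moment IS/OS     8 ancova   -0.0537 0.0001
inverse_difference_moment IS/OS    12 ancova   -0.0417 0.0000
                thickness IS/OS     8 t_test  -10.9540 0.0000
                thickness IS/OS    12 t_test   -9.8022 0.0000
```

The negative ANCOVA estimates say the diabetic group's GLCM correlation and
inverse difference moment are lower than controls after baseline
adjustment — the signature of finer, less spatially correlated speckle —
and the thickness t-tests act on percent-of-baseline values, whose group
means at week 8 recover the injected effect (`control 99.9%` vs
`T2D 89.0%` of baseline).

## Command line

```bash
octex simulate -o data/ --seed 7 --effects diabetic   # synthetic cohort
octex analyze --manifest data/manifest.yaml --out results/
octex features --volume scan.tiff --boundaries scan.csv --out features.csv
octex fixtures -o fixtures/
```

`analyze` writes `features.csv`, `thickness.csv`, `stat_results.csv`,
`summary.csv` and `run_metadata.json`; reruns on identical inputs are
byte-identical.

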