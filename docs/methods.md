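# Methods

This note documents the models, conventions and numerical choices behind
`octex`, in the order the pipeline applies them, together with what the
synthetic phantoms do and do not establish about real data.

## Coordinate and file conventions

A volume is indexed `(bscan, ascan, depth)`, 0-based, with depth increasing
from the inner (vitreal) side outward. On disk a volume is a non-compressed
multipage greyscale TIFF, one page per B-scan; by default page rows are
depth samples and columns are A-scans, with a flag to transpose (vendor
exports differ and the choice is echoed in logs). Boundaries are CSV tables
of floating-point pixel depths, one row per `(interface, bscan, ascan)`;
sub-pixel interfaces are kept because segmentation networks are typically
sub-pixel and rounding would bias thin layers. Cohort metadata lives in a
YAML/JSON sidecar manifest rather than TIFF tags, keeping image files
tool-agnostic. Round-trips are lossless: bit-exact for 8/16-bit volumes,
exact for boundary depths.

Seven ordered interfaces delimit six structures: NFL-GCL, IPL, INL, OPL,
ONL, IS/OS. Validation is report-based (every violating pixel listed), not
exception-based, so a cohort run can skip and count bad scans.

## Thickness

Layer thickness at `(b, a)` is `depths[k+1] − depths[k]`; the total retina
is interface 6 minus interface 0, which telescopes to the sum of the six
layers identically — an invariant the tests enforce on random boundary
sets. The per-eye summary is the unweighted mean over the full en-face
grid; no ETDRS-style sectorization is applied, since a single scanned
region per eye is assumed. With the default `axial_scale = 1` thickness is
reported in pixels; a µm/px scale converts to micrometres. Percent of
baseline is `100 · (v_t / v_0)`, computed ratio-first so identical inputs
give exactly 100.

`fallback_segment` is a deliberately simple intensity-based segmenter
(Gaussian smoothing, seven strongest peaks of the mean axial gradient,
per-A-scan windowed refinement with parabolic sub-pixel interpolation,
monotonicity enforced). It exists so phantoms can be analysed "blind"
without ground truth; it is not a clinical-grade method and no claims about
segmentation quality rest on it.

## Mean-value fundus projection

Pixel `(b, a)` of a layer's MVF image averages the volume samples at
integer depths in `[⌈upper⌉, ⌈lower⌉)`. The half-open ceiling rule was
chosen because it is bit-reproducible for sub-pixel boundaries and makes
adjacent layers partition every A-scan — no sample is counted twice or
dropped, and no partial-voxel weights are needed. Pixels with fewer than
`min_samples` (default 1) contributing samples are masked, not zero-filled,
so structural zeros never mix with tissue signal in the texture stage. The
sum is taken strictly inside the band, making the projection exactly local:
intensities outside a layer cannot perturb its MVF even at the level of
floating-point rounding. No lateral smoothing, vessel-shadow removal or
contrast normalization is applied before texture analysis; any
preprocessing must be explicit.

## GLCM texture features

Quantization maps masked MVF intensities linearly onto grey levels
`1..N_g`; min–max mode sends the masked minimum to level 1 and the maximum
to `N_g` (values on a bin edge join the upper bin; a constant image maps
to level 1), which makes every downstream feature invariant to positive
affine intensity transforms — a desirable property given that OCT
intensity scales are device-dependent. A fixed-range mode is available when
absolute calibration across eyes is wanted instead.

Defaults: `N_g = 64`, distance `d = 1`, the four standard directions
(0°, 45°, 90°, 135°) accumulated into a single matrix, symmetrized by
adding the transpose before normalization. These are the most common GLCM
settings in the radiomics literature; published texture values are not
comparable across studies without them, so all are configuration and are
echoed into every feature CSV header. Only pixel pairs with both endpoints
inside the validity mask contribute; `n_pairs` records the directed-pair
count and a matrix with no valid pair is flagged degenerate (features
become NaN markers).

The 20 features follow the canonical definitions with levels indexed
`1..N_g` and all logarithms base 2 (`0·log 0 := 0`). Three deliberate
resolutions of well-known ambiguities:

- `sum_variance` is centred on `sum_average`, not `sum_entropy`,
  correcting the dimensional inconsistency in the original formula table.
- `difference_variance` is the variance of the difference histogram about
  its own mean, not about zero.
- Degenerate single-level matrices use `correlation := 1` and `imci := 0`
  (both marginal variances/entropies vanish), and the `imcii` radicand is
  clamped at zero, keeping the feature vector finite on constant regions.

Compound names in common use ("homogeneity", "uniformity", "energy",
"inertia") are recorded as aliases; note that "homogeneity" is ambiguous
between the angular second moment and the inverse difference moment, and
this package treats IDM as the homogeneity-like quantity in its own
documentation. The implementation is vectorized; its independent check is
a literal-loop brute-force oracle (in the test suite) against which all 20
features agree to 1e-10 relative error on random matrices, plus a
cross-check of the co-occurrence counting against scikit-image on unmasked
images.

## Statistics

One model per (measure, layer, follow-up week), mirroring per-timepoint
reporting practice; no repeated-measures or mixed model is fitted.

**ANCOVA.** `value_t = β0 + β1·group + β2·value_0 + ε` by OLS
(statsmodels), group coded control = 0, T2D = 1. `β1` is the
baseline-adjusted group difference; its two-sided p-value comes from the
coefficient t-test (F = t² is reported as the statistic). Complete-case:
animals missing either timepoint are dropped and counted. At least 3
complete animals per group are required; a response with zero variance is
a degenerate-model error. Under a perfect noiseless fit the p-value is
defined as 0 for a non-zero coefficient.

**Gated two-sample test.** Shapiro–Wilk per group; both p > 0.05 routes to
the pooled-variance two-sided t-test, otherwise Mann–Whitney U (exact
enumeration when both n ≤ 20 and there are no ties, normal approximation
with tie correction otherwise). Constant samples, for which Shapiro–Wilk
is undefined, route to Mann–Whitney with a warning.

Summaries report mean ± SEM (`sd/√n`, ddof = 1, NaN for n = 1) and the
box-plot five-number summary with linearly interpolated quartiles. No
multiplicity correction is applied by default, matching the uncorrected
per-cell reporting convention of the study design emulated here;
Benjamini–Hochberg FDR is available behind a flag. Monte-Carlo calibration
(2,000 replicates, n = 20/group) places the empirical type-I error of both
families within [0.04, 0.06] at nominal α = 0.05.

## Synthetic phantoms and cohorts

**Phantom.** Six layers of configured thickness (defaults 34/30/25/18/40/24
px under a 30 px margin in a 256 px A-scan, reflectivities alternating
bright/dark as in real retinal OCT with a hyper-reflective IS/OS band) are
stacked below a shared low-frequency undulation surface, so thickness
profiles are preserved exactly; the undulation is rounded to whole pixels
so the rendered volume agrees exactly with the reported float boundaries.
Within a layer, intensity = reflectivity × speckle, where speckle is a
unit-mean gamma field (contrast = std/mean, default 0.35) smoothed
laterally to the configured correlation length (default 1.5 px), rescaled
to restore the target contrast, and clipped at a small positive floor;
axial correlation is one pixel. This is the simplest model whose
first-order and second-order statistics are independently tunable — the
two axes GLCM features measure. It is *not* a physical OCT forward model:
no PSF, attenuation, shadowing, vasculature or log-compression, so passing
tests demonstrate algorithmic correctness and sensitivity, not performance
on real scans.

**Cohort.** Two groups at weeks 0/4/8/12. Animal-level multipliers on
layer thickness (SD 5%), reflectivity (5%) and speckle correlation length
(10%) persist across weeks — this is what makes the baseline covariate
informative, without which the ANCOVA would degenerate to a t-test.
Visit-level multipliers model session-to-session measurement variability
(thickness SD 0.5% per layer, correlation length 3%); the thickness value
reflects segmentation/repositioning reproducibility of small-animal OCT
rather than the larger between-animal biological spread real cohorts show,
so recovered percent-of-baseline means are correspondingly tight.
Disease effects are per-(layer, week) multiplicative factors on thickness
(with per-animal response jitter, SD 1 pp), speckle correlation length and
contrast, applied to the T2D group; week 0 is pre-induction and must stay
at unit factors. `default_diabetic_effects()` encodes an early-DR-like
template: a few percent thinning emerging at weeks 8/12 (strongest in INL
and IS/OS), speckle coarsening in IPL and refinement in IS/OS. The
test-scale geometry is 64×64×256 voxels with 10 animals/group so the whole
pipeline runs in tens of seconds; acquisition-scale 512×512×1024 is a
configuration away.

All generators are pure functions of configuration + seed (bit-identical
reruns); scan-level seeds derive from the master seed.

## End-to-end verification choices

- Directional recovery uses the four features whose response to speckle
  correlation length is monotone by construction (GLCM correlation, IDM,
  INN, IDN) and checks sign and significance in the injected (layer, week)
  cells at n = 15/group; entropy- and mean-level features also respond but
  their direction depends on the quantizer's interaction with the gamma
  skew, so they are not used as sign anchors.
- The null-cohort significant fraction is compared against a band of
  0.5–12.5% around the nominal 5%: the 360 tested cells are strongly
  correlated within a layer (20 features of one image), which inflates the
  variance of the observed fraction well beyond the independent-binomial
  value.
- Problem sizes in the acceptance script (200 oracle matrices, 100
  boundary sets, 2,000 Monte-Carlo replicates, cohorts of 15–20 per group
  at 64×64×256) were chosen as the smallest sizes at which the quantities
  of interest are statistically stable.

## Known limitations

- No en-face registration between timepoints; the same retinal region is
  assumed re-imaged.
- No masking of low-quality A-scans beyond layer support.
- The speckle phantom's amplitude statistics are gamma, not the
  fully-developed Rayleigh/K family of coherent imaging; contrast and
  correlation length are matched, higher moments are not.
- One model per timepoint ignores within-animal correlation across
  follow-up weeks beyond the baseline covariate.
- `fallback_segment` assumes axially layered contrast with seven detectable
  gradient peaks; it fails loudly otherwise.
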