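# Methods

## The measurement problem

Canopy nitrogen concentration (CNC) is the total nitrogen of the
first fully unfolded sugarcane leaves, in % of dry mass, measured by
Kjeldahl titration: TN% = (V₁ − V₀)·C·0.014/m·100, with V₁ the acid
volume consumed, V₀ the blank, C the acid molarity and 0.014 g the
nitrogen mass equivalent of 1 mmol of acid. The analysis asks whether
5-band canopy reflectance measured from a drone can predict CNC and
recover the irrigation treatment of a plot.

## Synthetic trial generator

The real trial (12 plots with concrete partitions: 2 irrigation x 4
fertilizer treatments plus 4 blanks with neither input; 3 sampling
areas per plot; 9 grids per area; 324 grid samples) is emulated by a
single-latent-factor model:

    vigor  = b_w·W + b_f·F + b_wf·W·F + ε_v
    cnc    = cnc_mean + cnc_slope·vigor + ε_c
    band_b = baseline_b + slope_b·vigor + ε_b   (clipped to [0.001, 0.999])

with independent Gaussian noise per grid. Defaults (all in
`GeneratorConfig`):

| parameter | default | why |
|---|---|---|
| b_w | 1/300 per m³/ha | full irrigation contributes 1.0 vigor unit |
| b_f | 0.5 per relative rate | fertilizer spans ~0.45–0.6 vigor units |
| vigor noise sd | 0.2 | within-treatment grid variability ≈ 1/3 of the irrigation contrast |
| cnc_mean, slope, sd | 1.7 %, 0.35, 0.05 % | CNC ≈ 2.0 ± 0.2 %, a realistic leaf-N range for elongating sugarcane; keeps hold-out RMSE on the 0.05–0.2 % scale |
| band baselines (B,G,R,RE,NIR) | .05, .08, .07, .25, .45 | typical green-canopy reflectance |
| band slopes | −.015, −.010, −.030, +.040, +.100 | visible darken, red-edge/NIR brighten with vigor |
| band noise sd | 0.01 | sensor + surface heterogeneity |

The band slopes were chosen analytically, before any model fitting,
to reproduce the documented correlation-sign structure of a healthy
canopy: irrigation correlates negatively with B, G, R and positively
with RE and NIR; and among the pigment indices SRPI (B/R) and NGBDI
((G−B)/(G+B)) correlate positively while NPCI ((R−B)/(R+B))
correlates negatively. The sign of d(NGBDI)/d(vigor) equals the sign
of B·G′ − G·B′, so blue must darken proportionally faster than green
(here B′/B = −0.30 vs G′/G = −0.125); SRPI rises because red darkens
faster still (R′/R = −0.43). A closed-form population correlation
implied by these coefficients over the 12-plot design is used as the
oracle in the generator's tests.

Randomness: one root seed spawns a child stream per plot in plot
order, so regenerating any subset of plots is reproducible.

What the generator does **not** emulate: spatial autocorrelation
between neighbouring grids, radiative-transfer band coupling
(PROSAIL-class physics), illumination/BRDF effects, and weather.
Passing tests therefore demonstrate the correctness of the
statistical machinery under a linear single-factor world, not
field-level accuracy; the real-data headline accuracies are not
reproducible without the original imagery.

## Image path

Radiometric calibration is the empirical-line method: per band,
ordinary least squares of the known tarp reflectances (defaults 5, 20,
40, 60 %) on their mean digital numbers; the line then maps every
pixel, clipped to [0, 1], NaN propagating. Canopy extraction replaces
an interactively trained decision tree with a two-rule threshold
classifier — NDVI > 0.4 and summed 5-band reflectance > 0.15 — which
reproduces the same soil/shadow exclusions deterministically; the two
thresholds are exposed and the classifier is not claimed to equal any
particular interactive segmentation. ROIs are rectangular in pixel
coordinates (0-based, half-open), subdivided 3x3 by default with
integer-rounded edges; grid means are unweighted arithmetic means of
masked-in pixels, and an all-masked-out grid yields a flagged
(valid = False, NaN) record rather than disappearing. Mosaicking and
georeferencing are upstream and out of scope. Raster I/O is plain
multiband TIFF via tifffile; band order is fixed B, G, R, RE, NIR.

## Vegetation indices

The ten-index registry is closed (exactly NDVI, MSRI, OSAVI, RVI,
SAVI, SIPI, SRPI, NPCI, RVI2, NGBDI). MSRI is implemented as
(NIR/R − 1)/(NIR/R + 1), the normalized simple ratio, which is
algebraically identical to NDVI for positive reflectance; the
duplication is intentional and kept as a regression test — detecting
such redundancy is precisely the selection stage's job. All formulas
assume strictly positive reflectance (guaranteed by the generator's
clipping and by masking), which keeps every denominator positive.

## Grey relational analysis and selection

Sequences are min-max normalized by default (GRA's conventional
preprocessing; z-score available). The grey relational coefficient
uses the two-level extrema over *all* comparison sequences (Deng's
standard formulation); a per-sequence variant is available behind a
flag for sensitivity analysis. ρ defaults to 0.5. Degenerate case:
if every Δ is identically zero, all GRDs are 1 by convention.

Selection is greedy by descending GRD with deterministic
name-ascending tie-breaks: accept iff GRD > 0.65 (strict) and |R|
with every accepted feature < ceiling. Two shipped presets differ
only in the ceiling: `strict` (0.9) enforces the conventional
"very high correlation" cutoff; `relaxed` (0.975) admits one
near-collinear pigment-index pair (SRPI with NPCI, |R| = 0.97 on the
benchmark trial), trading redundancy for a third visible-band
feature. On the benchmark GRD/correlation inputs the strict rules
select {SRPI, NGBDI} and the relaxed rules {SRPI, NPCI, NGBDI}; both
behaviors are regression-tested.

## Regression models

All inputs are z-scored and the target centred/scaled on
calibration-set statistics only; validation rows never touch the
fitted statistics (asserted by a leakage test that perturbs
validation targets). The 7:3 hold-out uses round-to-nearest for the
calibration size (324 → 227/97). PLS uses 6 latent components
(capped at the feature-set size in the experiment grid);
full-component PLS is verified against a closed-form OLS oracle.
"Hidden layer" counts are read as hidden-*unit* counts of a single
hidden layer throughout. The BPNN is textbook full-batch gradient
descent (sigmoid hidden, linear output, uniform [−0.5, 0.5] seeded
initialisation); it converges geometrically but can plateau in flat
least-squares directions of the hidden basis, which the tests treat
as convergence-to-tolerance rather than exact interpolation. The ELM
draws input weights/biases uniform [−1, 1] from the seed and solves
output weights by least squares; with hidden units ≥ samples it
interpolates noiseless data to machine precision. ELM validation
error can explode on small feature sets (the random hidden expansion
extrapolates wildly outside the calibration hull) — a known
characteristic, visible in the examples, not a defect.

## Classification

The SVM is a C-support-vector machine with RBF kernel, C = 10,
γ = 0.167 (≈ 1/6, read as the kernel coefficient — the only scalar an
RBF C-SVM takes), one-vs-one multiclass. The classification BPNN uses
a softmax output and cross-entropy. Folds are stratified on the
class label, shuffled by the seed, sizes within one per class; the
confusion matrix pools out-of-fold predictions over the 3 folds
(each sample predicted exactly once, row totals = full class sizes —
the pooling convention implied by benchmark row totals of 108).
Accuracies are computed in exact rational arithmetic and rounded to
one decimal percent only for reporting. Adjacency of errors is
defined on the ordered irrigation levels (positions differing by 1).

## Problem sizes and numerical choices

Tests and the acceptance script run the default 324-sample trial;
sign-structure checks use enlarged designs (2 520–5 040 grids), where
the generator's population correlations (|R| > 0.3) make sign-test
false failures vanishingly improbable (< 1e−6). The permutation null
for classification uses 40 label permutations. Tolerances: GRA
matches a brute-force oracle to 1e−12; PLS-vs-OLS to 1e−8; metric
percentages are exact to the reported decimal. Reflectance clipping
to [0.001, 0.999] preserves the positivity that ratio indices
require.

## Known limitations

- The generator's linearity means index/band feature sets are nearly
  informationally equivalent; real canopies differentiate them more.
- The canopy mask is a threshold rule, not a trained classifier; it
  is exact on constructed scenes, approximate on real imagery.
- No ordinal treatment of irrigation levels (a natural extension:
  ordinal regression would exploit the 0 < 180 < 300 ordering the
  adjacency analysis reveals).
- Synthetic accuracies (e.g. pooled SVM OA ≈ 72–78 % across seeds)
  characterise the generator's default signal-to-noise, not any real
  field.
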