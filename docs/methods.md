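# Methods

## Overview

`coagclass` implements an in-silico pipeline for discovering compact,
time-localized assays that discriminate two clinical groups from the
kinetics of tissue-factor (Tf)-initiated thrombin generation. The pipeline
has five stages:

1. **Cohort synthesis** — virtual patients are drawn as plasma-factor
   compositions (percent of physiological mean) from per-group lognormal
   distributions.
2. **Kinetic simulation** — each composition defines the initial condition
   of a mass-action ODE model of the extrinsic clotting cascade, integrated
   stiffly for 3600 s after a 5 pM Tf trigger.
3. **Featurization** — each trajectory set is converted into four feature
   sets: piecewise-cubic-Hermite (PCHIP) coefficients, 200-second moving
   averages, conventional thrombin-generation summary parameters, and the
   raw factor composition.
4. **Classification** — random forests with out-of-bag (OOB) accuracy
   estimation quantify how well each feature set separates the groups.
5. **Selection** — mean-decrease-in-Gini (MDGini) importances drive a
   species-selection heuristic, time-resolved significance profiles, and
   the evaluation of small species-at-window combinations.

## Kinetic model and integration

A reaction network is a list of species plus irreversible mass-action
reactions; reversible reactions in a model file are expanded into
forward/backward pairs at parse time so the flux law is uniform:
`f_j(x) = k_j * prod_i x_i^{s_ij}`, `dx/dt = S^T f(x)`. Michaelis–Menten
terms are deliberately unsupported — the clotting models this package
targets are pure mass action.

Integration uses SciPy's BDF with the analytic Jacobian assembled from the
stoichiometry. Defaults: `rtol = 1e-8`, `atol = 1e-14` M. Concentrations
span picomolar (the 5 pM trigger) to micromolar (prothrombin,
antithrombin), so the absolute tolerance must sit well below 1e-12 M.
Near-zero states can undershoot zero by round-off magnitudes (we observe
~1e-19–1e-21 M in late thrombin, consistent with reports for this model
class); such values are *not* clamped by default, because clamping alters
the stored trajectory that featurization sees. A `clamp_nonnegative` option
zeroes them when desired. The output grid is 3601 uniform points (1 s
spacing), which comfortably resolves the ~25.9 s PCHIP pieces (≥ 26 samples
per piece).

The correctness oracles are a first-order chain (closed-form matrix
exponential) and conservation laws. Those comparisons are run with
`atol = 1e-20`: at sub-picomolar chain concentrations the default 1e-14
bounds only absolute error, and a relative comparison at 1e-6 would be
meaningless. This is an oracle-test setting, not a change to the clotting
defaults.

## The bundled toy cascade

Shipping a full 34-species extrinsic-pathway model would require rate
constants not distributed with this package, so model files are user
supplied. For tests and demonstrations we bundle a reduced 21-species
cascade (`coagclass/data/toy_model.txt`) that preserves the architecture:
Tf trigger → extrinsic tenase (lumped into Tf-fVIIa) → fXa and fIXa →
thrombin feedback activation of cofactors V and VIII → intrinsic tenase
and prothrombinase → thrombin burst, with stoichiometric inhibition by
TFPI and antithrombin. Rate constants are order-of-magnitude choices, not
literature values. The toy reproduces the qualitative phenotype that
matters downstream — a sigmoidal thrombin burst (peak ~0.7 µM) terminated
by antithrombin, with [IIa] back near zero by ~2000 s — but its initiation
lag (~35 s to 2 nM thrombin) is compressed relative to the several-minute
lag of full models. All 8 varied factors, Tf, IIa and fXa are present, so
the complete pipeline runs end to end on it.

## Cohort synthesis

Groups are specified by arithmetic mean/SD percentages per factor. The
lognormal is parameterised by the method of moments on the arithmetic
scale: `sigma^2 = ln(1 + (sd/mean)^2)`, `mu = ln(mean) - sigma^2/2`, which
reproduces the stated mean and SD exactly in expectation. (Fitting on the
log scale instead would shift accuracies slightly; the moment-matched
choice is fixed here.) Factors are sampled independently — no inter-factor
correlation structure is imposed. Percentages map linearly to molar initial
conditions via the physiological means (fII 1.4e-6, fV 2.0e-8, fVII
1.0e-8, fVIII 7.0e-10, fIX 9.0e-8, fX 1.6e-7, TFPI 2.5e-9, AT 3.4e-6 M);
every non-factor species starts at zero except the Tf trigger (5e-12 M).

The default synthetic specification used in tests and demos is **not** a
clinical estimate: CAD has mean 100/SD 15 for all 8 factors; ACS differs
only in prothrombin (110/15), factor VIII (120/25), TFPI (90/15) and
antithrombin (90/15) — the four factors reported to differ between the
groups — with heavy distributional overlap so that classification accuracy
is informative. Real cohort tables (CSV or XLSX with columns `group, fII,
…, AT`) are read with strict-positivity validation.

## Featurization

*Normalization.* Each species' trajectory is divided by its reference
peak: the maximum it attains in a single simulation from the 100%
composition. Species never produced get reference 1.0 (logged), making
normalization a no-op for them. Conventional features are computed on raw
molar profiles, because "time to 2 nM thrombin" is an absolute threshold;
PCHIP and moving-average features use normalized profiles.

*PCHIP coefficients.* 140 uniform knots over [0, 3600] s give 139 pieces of
~25.9 s. The monotone cubic Hermite interpolant (SciPy `PchipInterpolator`)
is C¹ across knots and cannot overshoot on monotone data. Per piece the
local polynomial `C3 (t-t_i)^3 + C2 (t-t_i)^2 + C1 (t-t_i) + C0` yields 4
coefficients; `C0` is exactly the knot value. For a 34-species model this
is 34 x 139 x 4 = 18 904 features. Knot values are linearly interpolated
from the 1 s storage grid (error negligible at these sampling densities).

*Moving averages.* Window k covers [200k, 200(k+1)] s, k = 0..17, labelled
by its centre 100 + 200k s; the windows partition [0, 3600] exactly, so
200 x (sum of the 18 means) equals the trapezoidal AUC — a property the
tests assert to 1e-9 relative. Integration is trapezoidal on the storage
grid with interpolated window endpoints. 18 x 34 = 612 features.

*Conventional parameters.* 11 scalars: thrombin time-to-2 nM (first upward
crossing by linear interpolation; profiles that never reach 2 nM return
the right-censoring sentinel 3600 s, logged, so forests never see missing
values), AUC, peak level, peak rate, and both peak times for thrombin and
fXa (no threshold time for fXa). Rates are central finite differences on
the storage grid; tied maxima take the earliest time. The two thrombin
forms (IIa, mIIa) are featurized as separate variables wherever both exist.

## Random forests

501 trees per forest (odd, so two-class majority votes cannot tie), grown
to purity on bootstrap resamples, Gini criterion, `floor(sqrt(p))` features
tried per split, no class weighting (designs are balanced by
construction). OOB accuracy classifies each sample by the majority vote of
trees whose bootstrap excluded it; samples never OOB (probability ~0 at
501 trees) are excluded with a warning. Because accuracies fluctuate with
the bootstrap draw, results are mean (sample SD) over 50 independently
seeded runs; run r uses seed `base_seed + r`, and every base seed is
recorded in the manifest.

MDGini is the impurity-based importance: the sample-weighted Gini decrease
of every split on a feature, summed within a tree, scaled to the training
set size (the scale used by the classical R implementation), and averaged
over trees. It is invariant under strictly monotone feature transforms —
the tests assert exact equality of importances after log/cube transforms —
and a feature never split on scores exactly 0. A permutation-based variant
is available (`forest.oob_permutation_importance`) but is not the primary
measure.

The ensemble itself is scikit-learn's `RandomForestClassifier`; the package
asserts the contract (bootstrap, random feature subsets, Gini, OOB votes,
unnormalized impurity importances), not the internals.

## Species selection and time resolution

From the all-PCHIP classifier's run-averaged importances:

* **Criterion 1** — fXa and IIa are always selected (the classical assay
  readouts).
* **Criterion 2** — species are ranked by the *top-fraction mean* of their
  coefficient importances: the mean of the highest ~10% (`ceil(0.10 n)`)
  values. A single maximum is noise-prone; the full mean blurs species
  together. The top `n_global` (default 2) non-forced species are admitted,
  and the full ranking is reported so the cut can be inspected rather than
  guessed by a knee rule.
* **Criterion 3** — the same score restricted to pieces whose knot time is
  ≥ 3000 s (the last 600 s); the single best species is admitted. Species
  still active at the end of the simulated window have an uncertain
  post-simulation fate. The fraction is a parameter because reasonable
  variants (top-5 values, top-25 values) change which species stand out.

Time resolution uses the all-moving-average classifier: each selected
species gets its 18 window importances; best-k subsets take the k highest
windows (ties → earlier window, since an earlier assay is preferable);
combination classifiers re-run the forest on triples of best single-window
features across species and report a ranked table.

Importances are averaged over runs *before* any ranking — per-run rankings
are noisy and selection is meant to be deterministic given the averaged
table.

## Synthetic validation fixtures

Two generators underpin the statistical tests:

* a planted-feature matrix — Gaussian noise (n = 400, 100 features) with
  one feature shifted by 5 SD in one group; 5 SD is the smallest round
  margin that cleanly exceeds 95% OOB accuracy for this geometry;
* a planted-profile cohort (`synthetic_profiles`) — smooth bump + band-
  limited noise trajectories where chosen species get an extra group-
  specific bump supported on a known time interval, so window-localization
  and late-window selection can be checked against ground truth.

These fixtures validate the machinery, not the biology: they show that
*if* a species' dynamics differ in a time window, the pipeline finds the
species and the window. They say nothing about whether a particular
clinical contrast produces such differences — that depends on the kinetic
model and cohort statistics supplied by the user.

## Problem sizes and numerical choices

Default analysis settings follow the study conditions: 200 samples per
group, 3600 s, 3601-point grid, 139 pieces, 18 windows, 501 trees, 50
runs. The test suite and the acceptance script use reduced sizes where the
check does not pin them — pipeline smoke runs use 50 (or fewer) samples
per group, 101–201 trees and 2–5 runs; planted-fixture checks use 201
trees and 2–3 runs per seed — chosen so the full suite completes in
minutes while leaving the asserted effects far from their thresholds.
Forest-calibration checks keep the stated sizes (501 trees, 50 runs,
n = 400 with 100 noise features; 20 planted seeds).

Degenerate inputs are handled explicitly: zero-SD factors give point-mass
lognormals; constant features get zero importance; profiles never reaching
2 nM are right-censored at 3600 s; species never produced normalize by
1.0; samples never OOB are excluded from accuracy. Ties (equal window
importances, equal maxima) break toward earlier time, fixed and
documented.

## Known limitations

* The bundled cascade is a toy: absolute accuracies on it do not predict
  accuracies on a full 34-species model with clinical cohort parameters.
* Factors are sampled independently; real plasma compositions are
  correlated, which would change both accuracies and importance rankings.
* PCHIP coefficients of order 2–3 carry weak information by construction
  (monotonicity constrains curvature), so importance mass concentrates in
  C0/C1 — expected, but worth remembering when interpreting rankings.
* Reproduction of any specific published trajectory is tolerance-bounded,
  not bit-exact: solver tolerances and storage grids of other
  implementations are generally unstated.
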