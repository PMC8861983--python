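# Methods

This note documents the statistical models, the numerical choices and the
design decisions behind `rsamix`, and what the synthetic-data conditions do
and do not establish about real RSA data.

## Coordinate conventions and migration metrics

Migration is expressed in the usual hip RSA frame: x transverse, y
longitudinal, z sagittal; translations in mm, rotations in degrees.  Signs:
+y is proximal (stem *subsidence*, a distal migration, is a negative ty),
+ry is internal rotation, +rz varus and −rz valgus tilt.  The 6-DOF
decomposition of a relative pose uses intrinsic x→y→z Euler angles
(`rsamix.config.EULER_SEQ`).  The sequence is a convention, not physics: at
clinical migration magnitudes (a few degrees) alternative sequences agree
to the third decimal, but one sequence is pinned so that decomposition and
recomposition round-trip exactly.

`total_translation` and `total_rotation` are Euclidean norms of the
translation and rotation triples.  For composed rotations the Euler-norm
approximation to the true matrix rotation angle carries a second-order
error; within ~5° of total rotation it is below 1% (property-tested).
MTPM is the maximum displacement over an implant-surface point set.  The
shipped point cloud (`default_stem_points`) is a synthetic 160 mm tapered
stem silhouette standing in for manufacturer CAD geometry; MTPM only needs
a representative surface envelope, not an exact mesh.

The rotation-offset operator applies one Rodrigues rotation about a unit
axis in the x–z plane block-diagonally to the translation and rotation
triples, treating small Euler triples as rotation vectors.  This emulates a
misaligned RSA frame and preserves both scalar surrogates exactly.

## Marker quality control

ME is the residual of the least-squares (Kabsch) rigid superposition of
the two marker examinations, summarised as √(Σdᵢ²/(n−1)) — the n−1 RMS
convention common in RSA; the denominator is configurable.  CN is
`scale/σ_min`, where σ_min is the smallest singular value of the centred
marker matrix divided by √n (a per-marker RMS spread in mm) and
`scale = 100 mm` is a named configuration constant.  CN conventions differ
between RSA platforms, so the conventional acceptability threshold of 150
is meaningful only jointly with this scale; both ship as config defaults
(`ME > 0.35 mm or CN > 150` ⇒ examination unacceptable) rather than being
hard-coded.

Outlier screening uses quartile ± 1.5 IQR cut-offs with the type-7
(linear-interpolation) quartile estimator and strictly-beyond flagging.
The cut-offs for the emulated trial cohort (subsidence beyond 5.44 mm,
y-rotation beyond 5.52° internal / 4.32° external) derive from patient-level
data that are not public, so they ship as frozen constants; recomputation
from data is available as a pipeline option.  Outlier handling is always a
cohort *view* — the original and without-outliers cohorts are analysed side
by side, never destructively filtered.

## The doubly repeated-measures mixed model

Each subject contributes one change-from-baseline response per observed
(visit, axis) cell; with visits {12, 22, 48} and six axes the full grid has
18 cells.  The marginal model is y_i ~ N(X_i β, V[o_i, o_i]) with all
within-subject dependence in V.  Three structures are implemented:

- `kronecker_un` (default): V = T ⊗ A with unstructured visit factor T and
  axis factor A, identified by T[1,1] = 1.  This matches treating both
  repeated measures as unstructured while keeping the parameter count at
  (t(t+1)/2 − 1) + a(a+1)/2 = 26 — fittable at trial-sized n.
- `unstructured`: the free 18 × 18 (or smaller-grid) covariance, used for
  sensitivity analysis and as the nesting upper bound (its REML
  log-likelihood can never fall below the Kronecker fit's; tested).
- `diagonal`: independent cells, the classical-equivalence baseline.

Mixed units (mm vs degrees) need no rescaling for testing: the unstructured
axis factor absorbs scale.  For the blended "3D migration" LS-means
display, responses are first divided by each axis's pooled SD
(`standardize_by_axis`) so that millimetre and degree axes contribute
comparably; both the raw per-axis and the standardized blended LS-means are
reported, since there is no canonical way to average mm with degrees.

### Estimation

REML, profiling the fixed effects.  Covariance parameters are optimized on
a log-Cholesky scale (every iterate positive definite by construction) with
analytic gradients and L-BFGS-B, at most 500 iterations; non-convergence
raises a diagnostic error carrying the final gradient norm rather than
returning a silent bad fit.  Initialization is deterministic: the
pairwise-complete covariance of OLS residuals, projected to the structure
(no random restarts).  The REML objective trace is recorded and is
monotone non-increasing (tested).  Subjects are grouped by missingness
pattern so per-pattern linear algebra is vectorized.

Missing cells are assumed missing at random and simply absent from the
subject's likelihood contribution — no imputation.

### Inference

F-tests use the Kenward–Roger adjustment: the covariance of β̂ is inflated
for the estimated V, and a scaled F with approximate denominator df is
formed.  Derivatives are taken in the covariance-*element*
parameterization, in which unstructured and diagonal structures are linear
(the second-derivative term vanishes) and the Kronecker structure is
bilinear (its T×A cross second-derivatives are kept).  The covariance of
the covariance estimates is the inverse expected REML information.  Note
that KR is not invariant to nonlinear reparameterization: the Kronecker
fit's adjustment follows its own (T, A)-element parameterization, the
convention for doubly unstructured models.

Two exactness anchors are verified numerically: in the balanced single-
response case the group test reproduces the pooled two-sample t-test with
denominator df n₁+n₂−2 to 1e-9, and in the balanced complete six-axis
single-visit case it reproduces the two-sample Hotelling T² F-test to
1e-6.  A Satterthwaite approximation is provided as a cross-check (within
5% of the KR df in the tested designs) and cheap fallback for scalar
contrasts.

The treatment readout is: (i) one joint F-test of all retained
group-involving terms ("3D migration"); (ii) per-axis slices — the group
difference within each axis, averaged over visits with equal weights
(per-visit slices available); (iii) LS-means over requested margins with
KR-based CIs, equal to arithmetic cell means in complete balanced data
(tested).  Backward model simplification drops the currently removable
interaction with the largest KR p ≥ 0.05, highest order first, preserving
marginality; ties break deterministically by term name.

### The balanced fast path

Inside Monte Carlo sweeps the simulated data are balanced, complete and
single-visit.  There the REML optimum is the pooled sample covariance in
closed form and the KR joint group test *equals* the Hotelling T² F-test
(the exactness anchor above), so the sweep evaluates that closed form,
vectorized over thousands of replicates, instead of running the optimizer
57,000 times.  A dedicated test asserts the equality of the two routes.

## The Monte Carlo power study

Design: two groups of n = 30 drawn from a 6-dimensional normal; the only
group difference is a y-translation shift δ solving the two-sample
noncentral-t power equation for 80% power at α = 0.05 (δ is
scale-equivariant and verified against a direct noncentral-t oracle).
Before analysis both groups are rotated by the offset angle about a random
x–z-plane unit vector, drawn fresh each iteration.  Three analyses per
iteration: a Welch t-test on y-translation; Welch t-tests on total
translation and total rotation (reported separately and as either-rejects,
since a combination rule for "the surrogate analysis" is not canonical);
and the multivariate joint test on all six axes.  Default grid 0–90° in 5°
steps, 3000 iterations per angle.

The sweep uses common random numbers across angles: the same base draws
and rotation axes are re-rotated to each offset angle.  Each point remains
an unbiased power estimate with binomial MC error, while angle-to-angle
comparisons are paired — the affine invariance of the multivariate test
then appears as an exactly flat curve, and the scalar surrogates (which are
rotation invariants) as exactly constant ones.  The calibration (80% at 0°)
and null (α at 90°) anchors are checked with independent draws.

### The default covariance

The generating covariance of the emulated trial is not public, so the
default Σ is a documented stand-in, **not** a trial estimate: per-axis
variances (precision/1.96)², with one biological-variability multiplier of
3 on the SDs of the two dominant migration axes (ty, ry), correlation 0.3
among translations and 0.2 among rotations.  The multiplier was fixed by
closed-form analysis before any simulation: it makes σ_ty comparable to
the in-plane translation noise, so the univariate test decays markedly
beyond ~50° while holding ~80% near 0°, and gives the joint test a flat
power near 0.55 (≈0.48 in the zero-covariance worst case) — reproducing the
qualitative regime of the study this emulates (multivariate > univariate >
surrogates on angle average).  The exact published power percentages depend
on the unpublished covariance and are deliberately not targets.  A pilot
covariance can be estimated from data (`estimate_pilot_covariance`, pooled
within-group at 12 weeks) and passed in.

The two-proportion sample-size calculator uses the pooled
normal-approximation formula with unweighted p̄ = (p₁+p₂)/2, ceiling to an
integer; it is symmetric in the proportions and cross-checked against
exact binomial enumeration at the returned n.

## The synthetic trial generator

`generate_trial` emulates a two-arm RSA trial: 33 treated / 32 placebo
postmenopausal subjects, visits at 12/22/48 weeks.  Per-axis
change-from-baseline follows an early-settling saturating trajectory
A(1 − e^(−t/τ)) with τ = 8 weeks (≈78% of settling by the first follow-up,
matching the clinical picture that most migration happens early).  Subject
asymptotes are normal around axis-, arm- and BMD-class-specific means;
between-subject SDs (0.5 mm on subsidence, 1.2° on y-rotation, smaller
elsewhere) are plausible clinical magnitudes, not trial estimates.  The
treated arm's between-subject variance is multiplied by 0.6 by default,
emulating the observed variance-reduction effect of antiresorptive
treatment (directionally detectable by Levene's test; tested).  BMD classes
mix as 50/46/4% normal/osteopenia/osteoporosis per the screening
distribution of the emulated trial, and low-BMD subjects get 0.9 mm extra
subsidence asymptote.  The default treatment effect on mean migration is
zero (a clean null); effects are injected explicitly via `group_effect`.

Measurement noise is i.i.d. normal per visit with SD = precision/1.96,
reading the printed precision as the 95% repeatability interval of double
examinations; whether that half-width corresponds to the SD of one
measurement or of a difference (a √2 factor) is interpretation-dependent,
so the noise profile is a config field.  Outliers are a two-point mixture:
with probability 0.12 a subject's principal-axis asymptote is replaced by
cutoff × U(1.15, 1.8) beyond the shipped screening cut-off (subsidence or
internal/external y-rotation), which makes every injected outlier
individually identifiable — deliberately, so recovery tests are exact,
at the cost of not modelling heavy-tailed borderline cases.  Whole visit
records are deleted with probability 0.021.

What passing tests on these data do *not* show: robustness to non-normal
migration distributions, informative missingness, visit-time jitter,
marker occlusion correlated with migration, or outliers that straddle the
cut-offs.  The generator is a statistical emulation of trial structure,
not of radiographic physics.

## Pipeline

`run_pipeline` chains QC filtering (when ME/CN columns are present),
outlier screening (shipped or recomputed rules), the mixed model on the
original and without-outliers cohorts (joint test, slices, raw and
standardized LS-means, optional simplification), and the companion tests
(Levene at 48 weeks on subsidence and the scalar surrogates; Fisher exact
on per-arm outlier counts; Pearson correlations of early z-rotation with
subsidence and, when supplied, BMD change).  Companion tests are thin
wrappers over scipy routines — they are routine statistics, not the
package's contribution.  Reports are pure functions of their inputs
(hash-tested) and carry a provenance block (config digest, seed, version).

## Problem sizes in tests

The test suite's simulation studies use sizes chosen to make each check
statistically meaningful at interactive runtimes: full 3000-iteration
sweeps where the vectorized closed-form path applies (power properties,
size calibration at 1000 replicates), and 10–60 replicate studies of the
optimizer-bound checks (simplification behaviour, LS-mean coverage,
slice localization) on reduced grids (2 visits × 2 axes).  Assertion
tolerances follow binomial MC error at those sizes.

## Known limitations

- No random-effects terms beyond the structured residual covariance (no
  random slopes); GEE/Bayesian alternatives are out of scope.
- KR cost grows quadratically in covariance elements: the full 18 × 18
  unstructured fit is supported, but its KR adjustment (171 elements) is
  slow and intended for sensitivity checks on reduced grids.
- Model-influence diagnostics (e.g. restricted-likelihood distance) as an
  alternative to IQR screening are future work.
- Pose estimation from stereo radiographs, calibration-cage geometry and
  periprosthetic BMD imaging are explicitly out of scope: the package
  consumes 6-DOF migration values, not images.
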