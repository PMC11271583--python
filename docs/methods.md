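# Methods

## The normative model

Each voxel `v` of a subject's contrast z-statistic map is modelled
independently by Gaussian Bayesian linear regression on a shared covariate
vector `x` (age, sex, intracranial volume, acquisition and task-design
parameters, and a full set of site indicators):

    y_v = x' w_v + ε,   w_v ~ N(0, α_v⁻¹ I),   ε ~ N(0, β_v⁻¹).

Responses are standardised per voxel on the training sample; continuous
covariates are standardised on training statistics (reused verbatim when
encoding a test cohort); binary covariates are 0/1; categorical covariates —
instruction variant, stimulus set, and site — are dummy coded with the full
indicator set. No reference level is dropped: all sites are treated
symmetrically as covariates of no interest, and the ridge prior resolves the
resulting collinearity with the intercept (the design is never inverted
unregularised). The basis is linear; a polynomial expansion was considered
and not adopted because the cohort structure the generator emulates contains
only linear effects and the model's contract is the minimal faithful one.

Hyperparameters `(α_v, β_v)` maximise the log marginal likelihood
(evidence). Updates are EM-style —

    α ← p / (m'm + tr S),   β ← n / (‖y − Xm‖² + tr(X'X S))

— which never decrease the evidence, giving a clean monotonicity invariant
at the cost of more iterations than gradient or fixed-point schemes.
Optimisation starts at `α = β = 1`, stops at relative evidence change
below 1e-6, and caps at 200 iterations; voxels still moving at the cap are
flagged (`fit.not_converged`) and keep their last iterate. Because the
design matrix is shared across voxels, the whole fit is vectorised through
one eigendecomposition `X'X = QΛQ'`; all per-voxel posteriors are diagonal
in that basis, so fitting ~5,000 voxels takes well under a second.

Predictions use the full predictive variance `β⁻¹ + x'Sx`, de-standardised
to response units. The deviation Z-score is the observed minus predicted
activation over the predictive SD; on data the model describes it is
standard normal per voxel, which the test suite checks by KS tests, tail
frequencies at the |Z| > 2.6 threshold, and moment bounds.

### Evaluation metrics

Per voxel on held-out data: explained variance `1 − Var(resid)/Var(y)`
(negative values are reported, not clipped), standardised MSE
`MSE/Var(y)`, adjusted Fisher-Pearson skewness and excess kurtosis of the
deviation scores (0 for a Gaussian). Zero-variance voxels yield NaN and are
listed, never silently zeroed.

## Deviation maps and burden

NPMs are thresholded at |Z| > 2.6 with a *strict* inequality — "greater
than" is read literally, so a score exactly at the threshold is below it.
The same reading applies to the motion-QC rule: sessions are excluded when
mean relative RMS displacement is strictly greater than 0.5 mm.

Burden comparisons use a two-sided Mann-Whitney U with mid-ranks. For
`min(n1, n2) ≤ 8` the p-value is exact, by full enumeration of the
`C(n1+n2, n1)` group labelings (valid under ties, since the pooled rank
vector is fixed); otherwise a normal approximation with tie and continuity
corrections is used. Degenerate input (all values identical) returns p = 1
with a warning.

## Test-retest reliability

ICC(3,1) is the two-way mixed-effects, single-measurement *consistency*
form, `(MSR − MSE) / (MSR + MSE)` for two sessions, computed from ANOVA
mean squares vectorised across voxels and cross-checked against pingouin in
the tests. Session change is summarised by the mean within-subject
difference with a paired t-test; the fraction of voxels with p below α=0.05
is reported **uncorrected** — with ~5% expected under the null, the summary
is directly interpretable as excess session sensitivity — and the output
metadata carries that choice explicitly. The third measure is the per-voxel
between-session Pearson correlation, with an optional rho² > 0.3 display
mask.

## Sparse canonical correlation

The association between symptom-domain scores X (n×p) and unthresholded
deviation maps Y (n×q) follows the penalised matrix decomposition: maximise
`u'X'Yv` subject to `‖u‖₂ ≤ 1`, `‖v‖₂ ≤ 1`, `‖u‖₁ ≤ c1`, `‖v‖₁ ≤ c2`.
Updates alternate `u ← normalise(soft_threshold(X'Yv, δ))` with δ found by
bisection (tolerance 1e-8; δ = 0 when the unit-L2 update already satisfies
the L1 bound) and symmetrically for v; initialisation is the leading
singular pair of `X'Y`, making the fit deterministic, and the objective is
non-decreasing up to the bisection tolerance. u's largest-magnitude entry
is reported positive.

Penalty defaults are the fractions 0.9 (factor side, light) and 0.1 (voxel
side, heavy) applied to the L1 feasibility cap `sqrt(dim)` of each view —
the PMD convention, under which an L1 bound can actually bind (any unit-L2
vector satisfies `‖·‖₁ ≤ sqrt(dim)`). The heavy voxel-side penalty keeps
the selected voxel fraction well under 10% in practice. Columns are centred
on the training rows only (a flag adds unit-variance scaling; off by
default). Generalisation is the mean Pearson correlation of held-out
projections over ten 70/30 splits; significance wraps the *entire*
procedure — including fresh splits — in row permutations of X, with
`p = (1 + #{null ≥ observed}) / (n_perm + 1)`.

## The synthetic cohort generator

The generator produces the structure the analysis assumes, not a biological
claim:

- **Sites.** Six sites whose relative sample sizes (scaled 1/20 → 386
  subjects by default; `n_scale` rescales), age ranges, sex balance, and
  scan/task setup are patterned on the large public EFMT cohorts. All
  acquisition/task columns are site-constant, so they are perfectly
  collinear with the site indicators — the situation structure coefficients
  exist to handle. Ages are uniform within each site's range, which
  reproduces the mid-adulthood coverage gap of such consortia; ICV is
  log-normal (log-mean 14.2, log-sd 0.07, ≈1.5e6 mm³) — only its role as a
  covariate matters, not its exact law.
- **Truth model.** Per-covariate weight maps are Gaussian-filtered white
  noise (correlation length 3 voxels — activation and covariate-effect maps
  are spatially smooth) with class-specific scales (intercept 1.0, age 0.4,
  site 0.3, sex 0.15, ICV 0.1 z-units); the noise SD is the exponential of a
  smooth field (median 1, log-sd 0.25), giving heteroskedastic Gaussian
  noise. The default grid is 20×20×24 with an ellipsoidal mask (~5,000
  voxels), a desk-scale stand-in for 2 mm standard space.
- **Clinical cohort.** Latent symptom-domain factors (4 domains, unit
  variance, exchangeable correlation 0.3) shift activation through sparse
  compact loading blobs (≤10% of voxels each, unit L2, default 5%);
  multi-label diagnosis indicators are drawn at naturalistic prevalences.
- **Retest.** A second session keeps each subject's true signal and redraws
  noise with SD `sqrt(noise² + session²)`, adding an extra component inside
  a compact "signal-dropout" blob to emulate regionally unstable deviation
  scores. With zero extra noise and an equal seed the session reproduces the
  original bit-exactly.

All generators are bit-reproducible given (spec, seed); per-stage streams
derive from the master seed by fixed offsets. What passing tests on these
cohorts do **not** show: robustness to non-Gaussian noise, spatially
autocorrelated noise, nonlinear covariate effects, missing data, or
registration/preprocessing artefacts of real fMRI.

## Voxel linearisation and I/O

In-mask voxels are linearised in Fortran order (first grid axis fastest),
0-based, identically in every module; maps are NIfTI-1, written as 32-bit
floats with zeros outside the mask; tables are UTF-8 TSV with a header row.
Missing covariates are a hard error — no imputation is attempted.

## Problem sizes used in the checks

The statistical suites run at sizes chosen to make their bounds
statistically safe while staying desk-scale: deviation calibration on ~500
held-out subjects across ~5,000 voxels; explained-variance recovery at
n = 1,000 per arm; sparse-CCA detection at n = 217 patients with 1,000
permutations and q = 2,000 voxels; permutation-null calibration over 200
repetitions of 99 permutations at reduced size (n = 60, q = 40); reliability
at n = 200 subjects over a 3-point session-noise grid. Per-voxel bounds
(e.g. deviation mean within ±0.1) are checked at sample sizes where both the
training-estimation and test-sampling error keep the whole-map maximum
inside the band.

## Known limitations

- Gaussian likelihood only; no warped/non-Gaussian variant, so heavy-tailed
  or skewed voxels (e.g. under signal dropout) are flagged by the skew and
  kurtosis metrics rather than modelled.
- Sites are fixed effects; no hierarchical pooling, and a cohort from an
  unseen site cannot be scored.
- One canonical component; regularisation strengths are fixed heuristics,
  not tuned by cross-validation.
- The paired-t session summary is uncorrected by design; treat the
  significant-voxel fraction as descriptive.
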