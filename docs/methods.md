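# Methods

`mediaopt` implements a closed Design-Build-Test-Learn (DBTL) loop for
maximising a lipopeptide titre (surfactin C, reported relative to an M9
baseline) over a two-dimensional medium-composition space — glucose
(% w/v) and NH4Cl (mM) — together with the downstream analyses used to
interpret such a study.  Because the experimental data of this kind of
study stay with the labs that produce them, the package ships a
first-class synthetic study generator; every claim the test suite makes
is therefore a claim about the calibrated simulator, not about any real
fermentation.

## The loop

Iteration 0 designs seven media compositions by a centred Latin hypercube
(each axis split into 7 equal bins, one point per bin at the bin centre,
bin pairing a seeded uniform permutation).  Each batch is laid out on a
96-well plate as a randomized complete block design: 7 combinations, a
control (M9 salts without carbon/nitrogen) and an M9 reference, each
appearing exactly once in each of 6 contiguous blocks (the replication
level).  The Build/Test stages are simulated: per-well 1-minute
flow-injection traces whose peak area encodes the measured abundance.

The Test stage turns traces into relative abundances:

1. **Baseline.** Traces whose leading/trailing window medians differ by
   more than 0.5 % of the peak amplitude get an asymmetric-least-squares
   (AsLS) baseline: iterate `(W + λ DᵀD) z = W y` with second-difference
   penalty `λ = 1e6` and asymmetry `p = 0.01` (weights `p` above the
   baseline, `1 − p` below) until the weights stabilise.  The gate (rather
   than a hand-curated metabolite list) decides which signals "need"
   correction; it can be forced on or off.
2. **Integration.** Trapezoid rule on the baseline-corrected trace over
   the 1-minute window; negative residuals are kept (clipping would bias
   low-abundance wells upward).
3. **Outlier removal.** Within each treatment × metabolite replicate
   group, keep values in `[median − 1.5·IQR, median + 1.5·IQR]`
   (quartiles by linear interpolation); groups smaller than 4 pass
   unfiltered, because quartiles on fewer points are unstable.  The
   filter is a single pass; two coincident outliers in one group can mask
   each other, which is one reason the loop models per-condition noise
   explicitly (below).
4. **Normalisation.** Divide every kept area by the mean kept
   M9-reference area of the same batch and metabolite, so the M9 medium
   reads 1.0 by construction.

The Learn stage fits a Gaussian process to all condition-level data so
far: inputs are scaled to the unit square, outputs (relative titres,
already dimensionless and O(1)) are centred but not rescaled, and each
condition enters as its replicate mean with observation-noise variance
equal to the squared standard error of that mean — a fixed-per-point
heteroskedastic noise model.  The kernel is Matérn-5/2 with per-axis
lengthscales plus a small homoscedastic white term.  Hyperparameters
maximise the penalised log marginal likelihood (MAP-II) by seeded
multi-start L-BFGS-B under lognormal hyperpriors:

| parameter | median | sd of log | rationale |
|---|---|---|---|
| signal variance σ_f² | 0.5 | 0.15 | titres are M9-relative; their spread over the space is O(1) |
| lengthscales ℓ | 0.3 | 0.2 | media response surfaces vary on roughly a quarter of the design range |
| white noise σ_n² | 1e-3 | 1.5 | replicate noise is carried by the SEM terms; the white term only absorbs residual misfit |

The priors matter at this study's sample sizes (7–21 conditions):
unpenalised ML-II happily returns degenerate fits (a lengthscale at its
upper bound, i.e. a flat axis, or a collapsed signal variance) on
iteration-0 data, and later refits inflate σ_f² because adaptive sampling
over-represents the peak.  Either effect makes per-iteration uncertainty
maps incomparable.  With the priors, the posterior-sd maps shrink
monotonically across iterations, which is the behaviour the uncertainty
comparison is meant to expose.  Plain ML-II remains available
(`GPConfig(use_priors=False)`) and is what the parameter-recovery test
uses.  Predictions are computed in-package by Cholesky factorisation; the
reported sd is that of the latent mean (observation noise excluded), and
the full joint posterior covariance is available for acquisition
sampling.

The Design stage proposes the next batch by Monte-Carlo q-noisy expected
improvement.  For a candidate set, draw joint posterior samples of the
latent function at observed ∪ candidate points; per sample the
improvement is `max(0, max(candidates) − (max(observed) + ξ))` with the
incumbent itself sampled (hence "noisy"); the acquisition value is the
sample mean.  The exploration offset ξ defaults to 0.01 on the
standardized scale.  Batches are built greedily: a seeded scrambled-Sobol
pool (plus the current grid argmax) is scored candidate-by-candidate
jointly with the already-selected points under one shared set of draws,
the argmax is appended, and a minimum pairwise separation (0.02 on the
unit square) is enforced.  With no observations the incumbent is defined
as 0 on the standardized scale (pure-prior case, used by the quadrature
oracle test).  The closed-form single-point EI serves as an independent
oracle for q = 1.

Inside the loop the acquisition uses 1024 MC samples over a pool of 256
(the standalone default is 4096 over 2048); at these pool sizes the
proposals are indistinguishable in our checks and a full three-iteration
run takes under a second per seed.

## The synthetic study

**Titre landscape.** A sum of anisotropic Gaussian bumps plus a constant
floor, anchored algebraically (`f = a·g + b`) so that f(0.4 % glucose,
18.7 mM NH4Cl) = 1.0 exactly and the maximum is 2.6 at (0.8 % glucose,
50 mM NH4Cl) — i.e. a 160 % headroom over M9.  Default bump widths are
0.35 % glucose and 28 mM; the resulting far-field floor is ≈ 0.38, so a
"performance cliff" (relative titre < 0.5) exists by construction.  The
design space defaults to glucose ∈ [0.1, 2.0] %, NH4Cl ∈ [5, 120] mM,
containing both this optimum and literature optima at higher nitrogen.

**Replicate noise.** Measured areas are `value · (1 + ε)` with
ε ~ N(0, cv_eff²), cv_eff = 0.15 · (1 + 0.2 · value): the coefficient of
variation grows with signal, a simple heteroskedasticity model.  With
probability 0.01 a well's area is multiplied by 5 (an outlier).  The rate
is deliberately low enough that two outliers rarely coincide in one
6-replicate group, since coincident outliers mask each other in the
one-pass IQR filter.  Traces add a per-well linear drift (≤ 2 % of the
area scale) and white noise at 2 Hz over 60 s, with a Gaussian peak at
0.3 min (σ = 0.05 min).

**Metabolite panel.** 25 signal surfaces in four planted groups
(6/7/7/5) with sign pattern (−, −, +, +): amino-acid-like groups
anti-correlate with the lipopeptide and organic-acid groups.  Members
are built in two zones around the titre optimum, using the elliptically
normalised radius r (semi-axes 0.6 % glucose / 24 mM — the anisotropy
radius).  Inside r ≤ 1 every non-asymmetric member follows one shared
radial profile, so its gradient magnitude is angle-independent there;
group identity is carried outside by smooth random surfaces combining a
shared latent (weight `between_group_weight`, default 0.3, which fixes
the correlation sign), a group latent and an independent member latent
(`within_group_weight`, default 0.9).  Group latents are explicitly
residualised against the shared latent and one another on a reference
grid — independent smooth 2-D surfaces have so few effective degrees of
freedom that their spurious sample correlations (±0.3–0.5) would
otherwise drown the planted structure.  Exactly `n_asymmetric` members
(default 6) add a tapered dipole term (strength 2.0, taper σ = 0.75 in
r), giving them a strongly direction-dependent gradient profile.
Members are exponentiated so abundances are positive; Spearman-based
analyses are unaffected by that monotone map.  The resulting dendrogram
shows two sign-defined primary clusters subdividing into the four
groups.

**Growth.** Logistic OD600 curves `od0 + (K − od0)/(1 + e^{−r(t − t_mid)})`
with od0 = 0.1, rate 0.012 min⁻¹, midpoint 700 min, sampled every 10 min
for 36 h.  The carrying capacity K is a smooth bump over composition
peaking at (1.2 %, 65 mM) — deliberately offset from the titre optimum so
titre/growth trade-offs exist but are not assumed to match any real
strain.  Growth features are the maximum and final OD of the (optionally
median-smoothed) curve.

**What the generator does not emulate:** instrument raw formats, SRM
transitions, isotope effects, plate-position (edge) effects, batch drift
between plates, non-Gaussian peak shapes, or any mechanistic link between
the panel surfaces and actual *Bacillus* metabolism.  Passing tests
demonstrate that the pipeline recovers what the generator planted under
realistic noise; they say nothing about absolute performance on real
fermentations.

## Downstream analyses

* **Uncertainty maps**: posterior sd of the latent mean on a 101 × 101
  grid; the scalar summary is the arithmetic grid mean, and model
  comparisons always evaluate identical grid points.
* **Performance cliff**: cells with predicted relative titre below 0.5;
  the boundary polyline comes from marching squares at the threshold.
* **Best improvement**: `100 · (best condition-mean relative titre − 1)`,
  with the achieving composition; the model-predicted argmax is reported
  separately.
* **Correlation structure**: Spearman (mid-rank ties) across signals;
  agglomerative clustering on distance 1 − ρ with average linkage; flat
  labels by cutting at k = 4.  Constant columns yield missing
  correlations with a warning and are rejected by the clustering step.
* **PCA**: column-centred (default unit-variance) SVD; explained-variance
  fractions from squared singular values; the largest-magnitude loading
  of each component is made positive so signs are deterministic.
* **Pareto trade-off**: predicted (titre, max OD) at seeded uniform
  compositions; the non-dominated set under joint maximisation, verified
  against an O(n²) dominance oracle in tests.
* **Directional anisotropy**: from a centre (by default the titre model's
  grid argmax; configurable, and analyses of the synthetic panel use the
  planted optimum), straight paths to the ellipse with semi-axes 0.6 %
  glucose / 24 mM at 36 angles, 100 points per path; 0° is a pure glucose
  increase, 90° pure NH4Cl.  The per-angle gradient is the mean of
  successive finite-difference slopes against normalised arc length.
  Straight radial paths are used rather than level-curve-orthogonal
  trajectories; for the radii involved the two coincide to first order
  around a maximum, and straight paths are well-defined even where the
  surface is flat.  The asymmetry index is
  `(max|g| − min|g|) / (mean|g| + ε)` over angles, with signals above 0.5
  reported asymmetric together with their dominant direction.  The index
  is scale-free, which makes it unstable for signals whose mean gradient
  is near zero when the centre is slightly mis-specified; with the exact
  centre a radially symmetric signal scores ~0 regardless.

## Numerical choices and degenerate inputs

Cholesky factorisations escalate a diagonal jitter (up to 1e-3 of the
mean diagonal) before failing; degenerate joint covariances in the
acquisition fall back to a clipped eigendecomposition with a warning.
Zero-variance outputs are centred with scale 1.  All random streams
derive from a single root seed through `numpy` SeedSequence spawning, so
runs are bit-reproducible and layouts are stable under block-count
changes.  Loop states serialise to a directory of CSV/JSON artifacts and
reload to models that predict identically.

## Problem sizes used in the checks

The acceptance-style checks run the study at its native scale — 3
iterations × 7 combinations × 6 replicates, 101 × 101 grids, 20 seeds for
loop-level claims, 200-point samples for panel-level claims — and the
whole suite completes in well under a minute of CPU.
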