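# Methods

## Model

A *linear law* of a scalar series `z_1..z_k` at embedding order `l` is the
unit vector `v ∈ ℝˡ` minimising `‖Av‖²`, where `A` is the `(k−l+1)×l` Hankel
trajectory matrix of overlapping windows.  Since `‖Av‖² = vᵀSv` with
`S = AᵀA`, the minimiser is the eigenvector of the smallest eigenvalue of the
symmetric positive-semidefinite Gram matrix; that eigenvalue is the law's
*residual* and equals the squared recurrence violation over all windows.  The
construction assumes nothing about the generating process; it is informative
exactly when the series is well approximated by a low-order linear recurrence
(sums of damped/sustained sinusoids, polynomials, exponentials).

The transform assumes instances of the same class share approximately
conserved linear relations per channel, and that those relations differ
between classes.  It does not assume equal series lengths, balanced classes,
stationarity, or alignment in time — the Gram matrix is always `l×l`
regardless of `k`, and laws are invariant to time translation of the window
set.

### Invariances

- **Amplitude scaling** `z → αz`: `S → α²S`; eigenvectors (laws) unchanged,
  residual ×α².
- **Offset / linear drift**: constants and linear trends are themselves
  solutions of low-order recurrences (`(1,−2,1)` annihilates both).  A law
  extracted from a distorted training series annihilates the distortion
  subspace of *that* series as well; the per-class minimal-variance selector
  then matches each test instance with the training law whose distortion
  profile fits best.  This is also why extending the training set never hurts
  other classes: selection is class-local.
- **Noise**: enters the Gram matrix at second order; the smallest eigenpair
  moves continuously with the perturbation, so recovery degrades gracefully
  (and measurably — see the monotone-degradation check).

## Pipeline

1. `fit(train, l)`: law of every (instance, channel) series → per-channel
   bank `Vʲ` (`l×τ`), columns labelled by class.
2. `project`: `S^{te,j} Vʲ` for each test instance/channel (`l×τ`).
3. `select_min_variance` (selector `f`): per class, the column with minimal
   sample variance over its `l` entries; ties go to the lowest column index.
4. `aggregate` (`g₁`, `g₂`): |mean| and sample variance of each selected
   column → `m·c` features per aggregator, ordered channel-major then class.

Only the test set is transformed; the training set's sole role is the bank.

## Parameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| `l` (order) | embedding window length | 30 (CLI) | resolves dynamics up to order `l−1`; 30 suits 480-sample channels. Must satisfy `2 ≤ l < k`; larger `l` raises cost `O(l²k + l³)` and, past the dynamics' true order, admits spurious null directions |
| selector variance | sample (`ddof=1`) | fixed | any fixed estimator yields the same argmin; sample variance used consistently in `f` and `g₂` |
| `absolute_mean` | report \|mean\| in `g₁` | on | signed means of near-annihilated columns fluctuate around 0; the magnitude is the informative part. A switch restores raw means |
| sign convention | largest-\|coefficient\| entry positive | fixed | laws are defined up to sign; a deterministic convention makes runs bit-reproducible. Downstream features are sign-invariant |

## Numerical choices

- Gram matrices are symmetrised as `(S+Sᵀ)/2` before decomposition; symmetry
  is enforced to 1e−10 relative on input.
- Eigendecomposition via LAPACK's symmetric solver in ascending order; for a
  degenerate smallest eigenspace the solver's first basis vector is used —
  deterministic, and any null-space basis vector is a valid law inside the
  quadratic forms that consume it.
- Tiny negative eigenvalues from floating point are clipped to 0.
- No centering or standardisation before embedding (an optional per-series
  z-score switch exists, default off).
- Ties in the minimal-variance selection break to the lowest column index.

## Synthetic data generator

Each class is, per channel, a linear recurrence whose characteristic roots
are unit-modulus conjugate pairs (sustained oscillations at class- and
channel-specific frequencies; odd orders add a real root at 1).  A minimum
pairwise root distance of 0.05 between classes on the same channel keeps laws
distinguishable.  Series are simulated by direct recursion from random
initial conditions with a 200-step burn-in, normalised to unit RMS, then
passed through distortion operators applied in a fixed order: longitudinal
rescale (linear interpolation), amplitude scale, linear drift, offset,
discontinuity jumps, additive Gaussian noise.  One seed drives the panel;
each instance derives its stream from `(seed, instance_counter)`, so
extending a panel never perturbs existing instances.

The `arem-mimic` preset reproduces the *structure* of a 7-activity,
6-channel, 480-sample wearable-RSS dataset (counts 15/15/15/15/15/7/6 = 88)
with additive noise at 5 % of signal RMS.  It emulates shape and difficulty
drivers, **not** radio-propagation physics or the real dataset's
class-conditional distributions: a perfect score here shows the transform
separates recurrence-governed classes under noise, not that any particular
real-world accuracy will be achieved.  An opt-in `instance_variation` mode
adds per-instance amplitude/offset/drift nuisance for harder experiments.

## Benchmark protocol

The fixed split preset assigns the published per-activity test sessions
(8+8+8+8+8+4+3 = 47 of 88, 53.4 %).  The reference protocol cross-validates
classifiers **on the transformed test set only** (stratified fivefold),
matching how the transform's features are defined (only test instances are
transformed); a conventional transform-train/score-holdout mode is available
via `stratified_split` + user code but is not the default.  Each classifier
family gets a 30-candidate randomized search; the ensemble family splits its
budget 15/15 between bagged and boosted trees.  Search spaces: KNN
(`k ≤ 20` capped by fold size, weights, L1/L2), decision tree (depth ≤ 20,
leaf size, criterion), SVM (`C ∈ [1e−2, 1e3]`, `γ ∈ [1e−4, 10]`, rbf/linear;
features standardised), forests/boosting (20–200 trees, depth, learning
rate).  Accuracy is reported from the pooled CV confusion matrix, so
`accuracy = 100·trace/total` holds exactly.  Timings are reported for
information and never asserted on.

## Problem sizes in tests and acceptance

The acceptance script runs the full 88-instance, 480-sample preset for the
benchmark claim and `k = 120–150` panels for the structural, separation and
robustness checks; the noise-monotonicity check averages 50 seeds at
`c=2, m=1, k=120`.  These sizes were chosen as the smallest that exercise
each property cleanly and keep the whole script in seconds.

## Known limitations

- Laws capture *linear* autonomous structure only; classes distinguished by
  nonlinear or purely stochastic signatures (equal spectra, different
  higher-order statistics) are invisible to the transform.
- With `l` far above the dynamics' true order and noisy data, the smallest
  eigenvector is selected within a near-degenerate subspace; features remain
  discriminative (any near-null direction responds weakly for the true
  class) but individual law vectors are not interpretable as recurrences.
- The reference protocol cross-validates on transformed test features, so
  its accuracies are not generalisation estimates for a deployed
  train-once/predict-new-instance workflow.
- The incremental case (updating a bank with new training instances without
  refitting) is out of scope; banks are refit from the training panel.
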