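# Methods

## Model overview

The package composes three layers:

1. **GM(1,1)** — an exponential-trend model for short positive series.
   The accumulated series x⁽¹⁾ is assumed to follow the whitenization
   equation dx⁽¹⁾/dt + a·x⁽¹⁾ = b; its discrete counterpart
   x⁽⁰⁾(j) + a·z⁽¹⁾(j) = b (with z⁽¹⁾ the mean of consecutive cumulative
   values) is linear in (a, b) and solved by least squares over points
   2..n. Restoration uses the closed form
   x̂⁽⁰⁾(i+1) = (x⁽⁰⁾(1) − b/a)(1 − eᵃ)e^(−a·i); the first point is the
   observation itself, so its residual is structurally zero.
2. **Markov residual states** — the signed residuals of points 2..n are
   partitioned into r equal-width intervals over their range; the label
   sequence feeds a first-order Markov chain whose one-step matrix P
   predicts the next residual state from the current one.
3. **Whitened correction** — each state interval [Lⱼ, Uⱼ] is collapsed
   to vⱼ = αⱼLⱼ + (1−αⱼ)Uⱼ and the GM value is shifted by the expected
   correction under the propagated state distribution. The α vector is
   fitted by a Gauss–Newton iteration with a finite-difference Jacobian.

Assumptions worth keeping in mind: the underlying trend is a single
exponential (no structural breaks), residual dynamics are first-order
Markov and stationary over the sample, and the series is strictly
positive — both the AGO fit and MAPE require it.

## Conventions and degenerate inputs

- **Signed residuals.** State intervals must carry sign: the correction
  is additive, so an under-prediction state must push forecasts up and
  an over-prediction state down. "Absolute error" in the grey-Markov
  literature is read as the signed error throughout.
- **Boundary rule.** States are half-open [Lⱼ, Uⱼ) with the last state
  closed; a residual exactly on a shared bound joins the higher state.
  This makes labeling deterministic.
- **Anchor handling.** Metrics default to points 2..n
  (`mape_skip_anchor=True`): the anchor's zero error is a construction
  artifact, and including it flatters every model equally. A flag
  restores inclusion for comparability with conventions that keep it.
- **First correctable point.** Point 2 carries the first labeled
  residual and has no predecessor state, so it passes through
  uncorrected; corrections start at point 3. In-sample, the previous
  state is observed, so its hard indicator is propagated one step
  through P; out of sample the distribution keeps propagating.
- **Empty transition rows.** A state that never has a successor gets the
  uniform row 1/r, keeping P row-stochastic without inventing structure.
- **Identical residuals** (an exact fit) make equal-width states
  degenerate; the partition raises instead of fabricating zero-width
  intervals, and the pipeline reports the failing stage.

## Optimizer

The corrected series is affine in α, so the Gauss–Newton iteration is
essentially one exact linear solve: from α⁰ = (0.5, …, 0.5), build the
forward finite-difference Jacobian A (step Cᵢ = αᵢ/R with R = 200 by
default, floored at 1e−4 so αᵢ = 0 still perturbs), solve A·η ≈ G − F in
least squares, clamp α + η into [0,1]^r, and stop when the linearized
residual Q = ‖(G − F) − A·η‖² or ‖η‖∞ drops below 1e−8 (or after 100
iterations). Design choices made where the scheme was genuinely open:

- The evaluation function is computed in the step variable η (the
  linearized residual after the update), which makes the stopping rule
  consistent with the normal-equation derivation of the update.
- Clamping (projection) was chosen over rejecting out-of-box steps. On
  this affine objective the first step lands on the unconstrained
  optimum, so whenever that optimum is interior the iteration converges
  in two iterations and matches a box-constrained linear least-squares
  solve to ~1e−11 (tested against `scipy.optimize.lsq_linear`). When the
  optimum sits on the box boundary the undamped update may keep
  projecting without meeting the tolerance; the returned α is still the
  last clamped iterate and in practice at or near the constrained
  optimum. No line search or damping is added, keeping the plain update;
  monotone decrease of Q is therefore not guaranteed and not asserted.
- A state that never occurs as a successor contributes a zero Jacobian
  column; the minimum-norm least-squares update leaves such an
  unidentifiable αᵢ in place and a warning is logged.

## Synthetic data generator

`generate_grey_series` emulates two regimes:

- **Noiseless grey series.** The recurrence
  x⁽⁰⁾(j) = (b − a·x⁽¹⁾(j−1)) / (1 + a/2) satisfies the grey difference
  equation exactly at every point, so the least-squares fit recovers
  (a, b) to machine precision — the estimator's primary correctness
  gate. Note the inherent discretization bias of GM(1,1): such a series
  is geometric with ratio (1 − a/2)/(1 + a/2) while restoration uses
  e^(−a); the two agree to O(a³) per step, so restored values match the
  data exactly only in the small-|a| regime (below 1e−9 for |a| ≈ 1e−4
  at n ≈ 12). Parameter recovery is exact at any |a|.
- **Markov-switching offsets.** Additive offsets drawn from a seeded
  chain over (weight, offset) states; rows default to the normalized
  weights (i.i.d. switching) and an explicit transition matrix produces
  correlated regimes, e.g. [[0,1],[1,0]] for strict alternation. The
  chain starts from a uniformly drawn state, an uninformative stand-in
  for the stationary distribution. These series exercise residual-state
  recovery: with alternating ±c offsets the estimated one-step matrix is
  exactly the permutation matrix and correction strictly improves MAPE.

What the generator does **not** emulate: trend breaks (e.g.
policy-driven demand shifts), non-stationary residual dynamics,
observation noise with continuous support, or multi-series dependence.
Passing tests on synthetic data therefore certify the algebra and the
estimators, not robustness of the method on real series whose residual
process is not first-order Markov.

## Defaults and parameters

| parameter | default | meaning / rationale |
|---|---|---|
| r | 3 | residual states; smallest count giving under/on/over-prediction semantics with ~9 labeled residuals. `sweep_states` tries {3,4,5} and keeps the best in-sample MAPE (ties to smallest r). |
| m | 1 | transition step used by the pipeline; `estimate_transitions` supports general m. |
| R (step_ratio) | 200 | finite-difference step-length coefficient. |
| ε (tol) | 1e−8 | stopping tolerance on Q and ‖η‖∞. |
| max_iter | 100 | iteration cap; only boundary-optimum cases reach it. |
| min_fd_step | 1e−4 | floor preventing a zero step at αᵢ = 0. |
| horizon | 7 | forecast years emitted by `run`. |
| mape_skip_anchor | true | score points 2..n (see above). |

## Problem sizes

All bundled analyses run on n = 10 annual points; synthetic checks use
n = 8–15 with 20+ random parameter draws and 10 optimizer fixtures —
comfortable desk-scale sizes chosen because the method targets exactly
this short-series regime.

## Known limitations

- With ~9 labeled residuals, r = 5 leaves most transition counts at 0 or
  1, so P is largely uninformative and larger r mainly adds free
  whitening coefficients; the sweep's in-sample gains at high r should
  be read as partial overfitting.
- The in-sample correction uses the observed previous state, so
  in-sample MAPE understates out-of-sample error.
- The undamped Gauss–Newton update can fail to meet the tolerance when
  the optimal α lies on the box boundary (see above).
- Equal-width states tie the partition to the residual extremes, which
  a single outlier can stretch.
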