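# Methods

## Model and assumptions

The predictor assumes the density of each feature conditioned on time is
Gaussian with a smooth periodic mean and a **time-constant variance**. Both
assumptions are deliberate simplifications: normalized log expression is
approximately Gaussian at a fixed time, and a single variance per feature is
simpler and more robust than a time-dependent variance. The conditional
independence of the sparse components used at prediction time is knowingly
false (components share observations) but works well in practice; the
log-likelihood it produces should be read as a score, not a calibrated
probability.

Internally all times live on [0, 1) with period 1; user-facing interfaces
accept a `period` (default 24, i.e. hours) and rescale on the way in and out.

## Periodic smoothing spline

The time-dependent mean of a feature is a cyclic cubic P-spline:

- **Basis.** `n_knots` evenly spaced periodic cubic B-splines on [0, 1),
  built by folding a standard B-spline basis modulo `n_knots`. The basis is a
  partition of unity and every fitted curve satisfies f(0) = f(1) exactly
  (evaluation wraps its argument into [0, 1)).
- **Penalty.** A cyclic second-difference penalty on the coefficients
  (constants are unpenalized).
- **Smoothing selection.** Generalized cross-validation over a fixed grid of
  25 log-spaced penalty weights, 1e-8 to 1e4. The grid, not a continuous
  optimizer, keeps the fit deterministic and cheap; per-feature selection is
  vectorized across features that share a complete set of observations.
- **Defaults.** `n_knots = 3` suffices for sinusoid-like circadian profiles
  (a 3-dimensional periodic space captures a fundamental oscillation); raise
  it for sharper waveforms. The cosine-recovery tests use 10 knots because a
  3-knot cubic spline approximates a pure cosine only to a few percent.

The variance is RSS/n (denominator n, not n − df). Exactly reproduced values
would give zero variance and infinite likelihoods, so a floor of
1e-8 × (value range)² (1e-12 for constant features) is applied.

Missing training entries are dropped pairwise per feature; a feature with
fewer than 3 distinct non-missing times is an error naming the feature, never
a silent skip.

## Pattern matrix and penalized decomposition

The pattern matrix discretizes each mean curve at `m` evenly spaced
time-points (τ_i = (i−1)/m, default m = 12 matching 2-hourly sampling of one
cycle), centers each column over the time-points and divides by the feature's
noise SD. `m` caps the number of extractable components.

The rank-1 subproblem (maximize uᵀZv with ‖u‖₂ ≤ 1, ‖v‖₂ ≤ 1, ‖v‖₁ ≤ c) is
solved by alternating updates — u ← Zv/‖Zv‖₂, v ← S(Zᵀu, Δ)/‖S(Zᵀu, Δ)‖₂ with
entrywise soft-thresholding S — where Δ ≥ 0 is the smallest threshold meeting
the L1 budget, found by bisection (≤ 50 iterations, tolerance 1e-8 on ‖v‖₁).
v is initialized from the leading right singular vector of a dense SVD;
convergence is |Δd| < 1e-7 or 100 iterations. Numerical choices beyond the
published scheme:

- **Sign convention.** After convergence the factor is negated if the
  largest-magnitude loading is negative; argmax ties go to the lowest feature
  index. Output is therefore deterministic.
- **Tie-degenerate budgets.** When the largest |Zᵀu| entry is shared by k
  features and √k exceeds the budget c, no soft threshold can satisfy the
  constraint; the implementation then keeps the ⌊c²⌋ lowest-index tied entries
  with equal magnitude — the exact optimum restricted to the tie set, and the
  natural extension of the c = 1 "single coordinate" limit.
- **Support cleanup.** Loadings below 1e-11 × max|v| are clipped to exact
  zero so the reported support is meaningful.
- **Sequential extraction.** Before component k+1, Z is projected onto the
  orthogonal complement of u_1..u_k (left side only), which discourages
  correlated components without constraining the loadings. Candidate u's are
  re-orthonormalized against the basis before being added, and a numerically
  zero deflated matrix yields explicit null components (d = 0, empty support)
  rather than noise-driven factors.
- `sumabsv = inf` is accepted as a sentinel for unpenalized components
  (standard PCA of the pattern matrix); otherwise `sumabsv` must lie in
  [1, √p].

Variance explained is reported as d_k²/‖Z‖_F² with d_k measured on the
deflated matrix; in the unpenalized limit this equals σ_k²/Σσ².

## Prediction

The log-likelihood over the circle is evaluated on a 100-point even grid and
the best grid point is refined by bounded scalar minimization in its
bracketing interval (xatol 1e-7). The likelihood is periodic and typically
multimodal (a single local search would be unsafe); with smooth low-knot mean
curves the global basin is much wider than the grid spacing, and the combined
scheme agrees with a 10 000-point brute-force argmax to better than 2e-4.
Exact ties in the grid argmax resolve to the smallest t.

Missing values: training rows may have gaps — a missing entry contributes
nothing to the projection and the score is rescaled by the inverse squared
norm of the observed loadings (the least-squares projection coefficient on
the observed subset). Test observations must be complete on the predictor
features (the features with a nonzero loading in the first `n_spc`
components); anything else is an error naming the observation and feature.
Features outside the predictor set never influence a prediction.

## Defaults

| parameter | default | meaning |
|-----------|---------|---------|
| `sumabsv` | 2 | L1 budget per component; ~10–20 features each at p ≈ 500 |
| `n_spc` | 2 | components used for prediction; two capture sine+cosine phase |
| `m` | 12 | discretization time-points = max components |
| `n_knots` | 3 | periodic basis size per mean curve |
| `period` | 1 (library) / 24 (CLI) | native time units |

One component cannot distinguish rising from falling phase (its likelihood is
symmetric in time about the component's extrema), so `n_spc = 2` is the
practical minimum for accurate timing; additional components help only when
the data contain higher-order time patterns.

## Molecular-timetable comparator

Feature selection: periodicity is the maximum Pearson correlation with
cos(2π(t − φ)) over 200 candidate phases followed by bounded local
refinement; variability is the plain standard deviation across training
observations (the coefficient of variation is meaningless for data with
negative values). Defaults: periodicity ≥ 0.8 and SD at or above the 90th
percentile of all feature SDs — configurable, as the original criteria are
qualitative. Prediction standardizes the test observation by training
mean/SD and maximizes, over 200 candidate times plus refinement, the Pearson
correlation across features between the standardized values and each
feature's cosine value at the candidate time. With a single retained feature
the correlation is undefined and the dot product is maximized instead. The
reported objective is the achieved correlation — not a log-likelihood. This
template-correlation rule is one faithful reading of the original method,
which leaves weighting and outlier handling unspecified.

## Synthetic benchmark

`default_benchmark` emulates multi-organ circadian expression *after*
cross-batch normalization: 20 oscillatory features with phases evenly spread
over the cycle and amplitudes 1–3, 480 pure-noise features, 12 time-points ×
2 replicates × 3 groups (72 observations), Gaussian noise SD 0.5, and small
per-(group, feature) baseline offsets (SD 0.1) standing in for residual
batch effects. Group structure drives the leave-one-group-out design; the
generator does not simulate probe effects, gene–gene correlation, or
heteroscedastic noise, so passing benchmarks demonstrates correct parameter
recovery under the stated model, not performance on raw microarray data.
An optional `spline-perturbed` waveform adds a random second harmonic so
non-sinusoidal recovery is testable, and `group_amplitude_scaling_sd` adds
multiplicative per-group amplitude distortion as a robustness stress test.

Problem sizes throughout the test-suite and acceptance script (72 × 500
matrices, 10 simulation seeds, 100 optimizer instances, 10⁵ random pairs)
were chosen so the whole pipeline — spline fits vectorized across features,
12 rank-1 extractions per fit — completes in seconds while keeping
Monte-Carlo noise well inside the asserted tolerances.

## Known limitations

- No confidence interval on the predicted time; the likelihood curve
  (`keep_curve=True`) is exposed for users who want to inspect flatness.
- Independence of components is assumed, not enforced or tested.
- The constant-variance assumption can misweight features whose noise varies
  strongly over the cycle.
- Cross-study batch correction is out of scope: the model consumes already
  normalized matrices, and systematic shifts between training and test data
  translate directly into timing error.
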