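# Methods

This note documents the statistical model, the numerical choices, and
the limits of what the synthetic-data tests demonstrate.

## Models and fitting

Each curve supplies log10 molar doses `x`, responses `y` (ratios to
control, required positive), weights `w` (default 1) and its usable
point count `n`.  Non-finite or non-positive responses are dropped at
construction; a control measurement, which has no position on a log
axis, is anchored at `min(x) − control_offset` (default 2 decades)
where it pins the front plateau.  Points dropped this way lower the
curve's `n`, and every downstream quantity (dfd, s0, p) uses the
curve's own `n`.

The mean model is solved analytically (weighted mean).  The
log-logistic fit is a box-constrained non-convex problem — a steep
curve can model a step between any two adjacent doses — so a
multi-start scheme is used:

1. **Start grid.** pEC50 at 7 equally spaced positions across the
   experimental dose range, slope in {0.5, 1, 2}, plateaus from the
   10th/90th percentiles of `y` in both orientations (42 starts before
   deduplication).
2. **Variable-projection screen.** For fixed (pEC50, slope) the model
   is linear in the plateaus, so the conditionally optimal front/back
   and SSE have closed forms.  The screen ranks the start candidates —
   augmented with steeper slopes (4, 8, 16) to catch step-like optima —
   at negligible cost.  Because the flat curve is feasible in the
   linear subproblem, the screened SSE never exceeds the mean-model
   SSE.
3. **Polish.** The best `n_polish` (default 3) candidates receive a
   bounded local optimisation: L-BFGS-B with the analytic Jacobian for
   least squares, Nelder-Mead on the profiled likelihood for maximum
   likelihood (the profiled optimum over σ² is SSE/n, so both
   objectives share their argmin over the curve parameters).

Bounds: slope ∈ [0.01, 20], plateaus ∈ [1e−3, 1e6], pEC50 within the
experimental dose range ± 4 decades.  Convergence tolerance 1e−10 on
the objective, 500 iterations per start.

Large homogeneous batches (null simulations, decoys, and any group of
curves sharing a dose grid and weights) run through a vectorised
engine that performs the same screen (25 pEC50 positions × 7 slopes)
and polishes the top candidates with a projected Levenberg–Marquardt
iteration, all curves simultaneously.  Marquardt damping (λ·diag JᵀJ)
is used deliberately: it makes the iteration equivariant under affine
rescaling of the responses, so F-values of rescaled noise draws agree
to float precision.  Tests cross-check the batch engine against the
per-curve scipy path; both are deterministic (no randomness anywhere
in fitting).  On flat-noise curves the two engines agree on SSE to
better than 0.1% except for rare near-tied basins, where any iterative
fitter's outcome depends on its stopping point.

## Significance

`F = (SSE_M0 − SSE_M1)/SSE_M1 · n/k` with `k = 4`.  Its null
distribution is taken as `F(dfn=5, dfd(n), loc=0.12, scale=1)` with
`dfd(n) = (0.8 − correction(n))·(n − 2.5)` and
`correction(n) = 1/((n−k)^k/n + k)`.  These calibration constants are
adopted as given (they originate from large-scale flat-truth
simulation of the same fitting problem) and are not re-fitted here; a
re-fitting utility is out of scope.  The package verifies the
calibration empirically at desk scale: 20,000 fitted flat-truth curves
at n = 10 give a p < 0.05 fraction inside [0.04, 0.06] and a KS
distance to uniform below 0.02, and 50,000 simulations reproduce the
0.01 and 0.001 tail frequencies within 3 binomial standard errors.
Degenerate cases: SSE_M1 = 0 with SSE_M0 > 0 yields F = +∞ (perfect
fit); a perfectly flat dataset yields F = 0.

## Relevance score and classification

`s0 = fc_lim / sqrt(Q)` where `Q` is the `1 − alpha` quantile of the
**central** F-distribution with (5, dfd(n)); the relevance score is
`−log10` of the upper tail of `F_adj = 1/(1/√F + s0/|cfc|)²` under the
**shifted** null (loc = 0.12).  This mixed convention is intentional
and worth stating plainly: the central quantile in the s0 formula
reproduces the worked boundary values (0.13 and 0.214), while the
shifted tail makes the s0 = 0 score reduce exactly to −log10(p).  The
two requirements cannot be met by a single convention — with the shift
included in the quantile the second worked value becomes 0.211 — so
the default is mixed and both pieces are overridable
(`use_shifted_quantile`, `use_shifted_tail`).  `|cfc|` is used in the
denominator so down-regulations are penalised symmetrically, and
`F_adj = 0` by continuity when `cfc = 0` with s0 > 0.

A curve is called up/down when its relevance score reaches
`−log10(alpha)`; the explicit hyperbolic boundary form is provided and
is exactly equivalent (property-tested).  Consequences worth knowing:
no curve with `|cfc| < fc_lim` can ever be called, and because the
threshold sits at the shifted quantile `Q + 0.12`, a curve barely
above the fold-change asymptote additionally needs
`|cfc| ≥ fc_lim·sqrt(1 + 0.12/Q)` even at infinite F.

Non-calls split into `not` (intercept within fc_lim/2 of 1 — measured
in log2 space for symmetry with the fold-change asymptote, switchable
to linear — and mean-model RMSE ≤ 0.1, optionally also p ≥ a floor)
and `unclear` (everything else; typically high-variance curves).  The
"not" class is a heuristic for building clean negative sets, not a
statistical acceptance of the null.

## Decoy FDR

Per-curve sample variances `s² = SSE_M1/dfd(n)` (zero-residual curves
excluded) are resampled with replacement to generate flat-truth decoy
curves on the same dose grid, which run through the identical fit and
scoring stages.  The q-value of a target is the minimal estimated FDR
over all score thresholds at or below its own score, with "≥"
counting, self-inclusion, and an `N_targets/N_decoys` rescaling —
the standard conventions that keep q ∈ [0, 1] and monotone.  On
labelled synthetic mixtures (5,000 curves, 10% regulated) the estimate
at the 5% significance threshold tracks the true false-discovery
proportion within about ±20% per run.  At a hyperbolic boundary the
true FDP on such mixtures is a handful of counts (~0.5%), so only
aggregate, not per-run, agreement is meaningful at that scale.

## Synthetic data

The generator emulates a ratio-normalised screen: flat-truth curves
`y = 1 + e`, `e ~ N(0, σ²)`, and regulated curves from the
log-logistic model with front = 1, back = `2^cfc`, truth pEC50 drawn
at least one decade inside the dose grid (edge potencies compress the
observable fold change and would confound recovery tests), slope 1 by
default, and the regulation direction up/down with equal probability.
Per-curve σ comes from a truncated log-normal stand-in,
`log10 σ ~ N(−1.3, 0.35)` clipped to [0.005, 0.5] — a synthetic choice
representing the wide variance spread of deep proteomics screens, kept
in a single marked constant.  The default dose grid is 10 log-spaced
points over 5 decades ending at 100 µM (null-simulation grids use
half-log spacing over 4.5 decades, a typical screening design; the
calibration depends on the grid only through `n`).

What passing tests do **not** show about real data: the generator has
Gaussian, homoscedastic-within-curve noise, no missing-value
structure, no batch or acquisition artifacts, no correlation between
curves, and single-event sigmoidal truth.  Multi-phasic responses,
heavy-tailed noise, or systematic normalisation errors are outside
the model family and are not covered.

## Numerical notes and known limitations

* pEC50 recovery at n = 10, σ = 0.05, |cfc| = 1 sits near the
  information-theoretic limit: the CRLB standard deviation ranges from
  0.17 (centre of the grid) to 0.28 (one decade from the edge), so the
  ~91% fraction within ±0.3 observed for mixed-direction truths is
  close to the best any estimator could do; purely down-regulated
  curves (half the amplitude of up-regulated ones at the same |cfc|)
  recover at ~85%.
* Exponents are clipped at ±300 before `10**x` to avoid overflow at
  extreme slope×distance products; plateau clipping at the box bounds
  can very slightly bias screened starts for curves whose optimal
  plateaus are negative (possible only at noise far above the
  generator's range).
* Fold changes require positive model values; mode "control" compares
  against the unit control ratio instead of the lowest fitted dose.
  When a control point exists, the default "range" mode evaluates the
  model at the control pseudo-dose (the lowest point of the fitted
  range).
* Preprocessing order is median-centering → imputation (per-table
  0.5% intensity quantile) → control normalisation, each opt-in; rows
  with more than `max_missing` (default 4) missing responses are
  excluded, and curves with fewer than `min_points` (default 5) usable
  points are skipped with a logged reason.
* The CLI accepts `--threads` for interface stability but executes
  deterministically in-process; results are independent of it by
  construction.
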