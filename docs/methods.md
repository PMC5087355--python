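# Methods

## Model and assumptions

The incremental RBF network assumes the regression surface decomposes into
a dominant global linear trend plus localized, smooth departures.  The
linear part is fitted first by ordinary least squares; everything the line
misses is treated as a *residual signal* to be explained by a small
Gaussian RBF layer.  The key structural idea is where the RBF centers come
from: the residual axis is split into `p` fuzzy *contexts* (triangular
membership functions), and context-based fuzzy c-means (CFCM) clusters the
inputs *within each context*, so hidden units end up in the input regions
responsible for each band of the error — large positive residuals, near-zero
residuals, large negative residuals, and so on.  Points whose residual does
not activate a context get zero membership budget there and cannot attract
its prototypes.

This construction is sensible when (a) the linear backbone captures most
of the variance, (b) the nonlinearity is localized rather than global, and
(c) residual magnitude is informative about *where* in input space the
nonlinearity lives.  When those fail (e.g. heavy heteroscedastic noise or
globally curved response), the model degrades gracefully to the linear
backbone: the least-squares output weights can always be zero, so training
RMSE never exceeds the backbone's.

## Procedure

On min–max normalized features and target:

1. OLS backbone `z(x)`; residuals `e = y − z`.  The design matrix is
   checked for full rank; residuals have zero mean by construction.
2. `p ≥ 2` triangular contexts with peaks equally spaced over
   `[min e, max e]` (both endpoints included), half overlap, partition of
   unity.  Contexts are built on the *signed* residual: the sign separates
   under- from over-prediction regions, which is precisely the information
   the clustering should condition on.  Range-based (not quantile) spacing
   is used; evaluation-time residuals outside the training range clamp to
   the nearest edge so membership evaluation is total.
3. Per context `l`, CFCM with `c` clusters: alternating partition/prototype
   updates until `max |ΔU| < tol` or `max_iter` sweeps.  The partition
   update enforces column sums `Σ_i u_ik = w_lk` exactly; the objective
   `Q = Σ u^m d²` is non-increasing across sweeps (each half-step is an
   exact coordinate minimization).
4. The `c × p` prototypes become RBF centers.  Widths `σ_i` are the
   membership-weighted RMS distances of the data to each center —
   `σ_i = sqrt(Σ_k u_ik^m ‖x_k − v_i‖² / Σ_k u_ik^m)` — which keeps widths
   in data units and adapted to each cluster's spread.  Degenerate widths
   (below 1e−6, or undefined for an all-zero membership row) fall back to
   the mean pairwise distance between centers; if that is also zero the
   data carry no spatial scale and fitting fails loudly.
5. Output weights solve `min_g ‖e − Φg‖² + ridge·‖g‖²` in one pass.
   With `ridge = 0` (default) a rank-revealing solver returns the
   minimum-norm solution.  Prediction is `Y = z + E`, de-normalized.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `n_contexts` (p) | 3 | residual-axis granularity; 3–6 is the useful range, larger p thins out the extreme contexts |
| `n_clusters` (c) | 3 | prototypes per context; hidden layer has `c × p` units |
| `m` | 2.0 | fuzzifier (> 1 required); 2 is the universal fuzzy-c-means choice |
| `tol`, `max_iter` | 1e−5, 100 | CFCM stopping rule on `max |ΔU|`; typical convergence is 15–40 sweeps |
| `ridge` | 0.0 | optional Tikhonov term on output weights; the plain LSE can become ill-conditioned for large `c × p` on small training sets (test RMSE explodes while training RMSE keeps falling), and 1e−8 is a safe guard when exploring large grids |
| `normalized_rbf` | False | hidden activations already lie in (0, 1]; the flag switches to the normalized-RBF reading (activations divided by their per-sample sum) |
| `normalize_target` | True | both features and target are min–max scaled; reported RMSEs are always in original target units |
| `split_fraction`, `n_repeats` | 0.6, 10 | evaluation protocol: repeated random ~60/40 subsampling, train size floored |

The grid search is scored by **mean test RMSE**; cells whose fit fails
(a context covering fewer positively weighted points than requested
clusters) are reported as NaN with the reason attached, never silently
dropped, and the per-repeat lists keep length `n_repeats`.

## Numerical choices

- **CFCM initialization** (unspecified in the literature the model follows):
  uniform random partition matrix rescaled per column to the context
  budget, seeded; every stochastic path in the package is a pure function
  of the seed.
- **Zero-distance singularity** in the membership update: a point
  coinciding with a prototype takes its whole budget `w_lk` there; ties
  between coincident prototypes split it equally.
- **Empty clusters** (all-zero membership row after an update) keep their
  previous prototype rather than producing 0/0.
- **Zero-budget points** (`w_lk = 0`) keep `u_ik = 0` and are retained in
  the partition matrix for shape stability.
- Constant feature or target columns, degenerate residual domains
  (all residuals identical), rank-deficient designs, under-populated
  contexts and scale-free width estimation all raise explicit `ValueError`s
  instead of propagating NaN.

## Synthetic data

No public dataset exists for the patch-sensor HR/MI/EE setting, so the
package ships a seeded generator that emulates the structure the model
assumes: `EE = β₀ + β_HR·HR + β_MI·MI + Σ_j amp_j · exp(−[(HR−c_HR,j)² +
(MI−c_MI,j)²]/2w_j²) + N(0, σ_noise)`, with HR ~ U[60, 190] bpm,
MI ~ U[0, 6], β = (−3.0, 0.07, 0.6) kcal·min⁻¹ per unit, two bumps
(an extra cost of +1.5 near (HR 150, MI 4.5) and a −1.0 economy dip near
(95, 1.5), widths 12 and 10), σ_noise = 0.2 kcal·min⁻¹, and n = 252 —
magnitudes chosen to resemble submaximal walking/running intensities
(EE roughly 1–12 kcal·min⁻¹).  Gaussian bumps are used deliberately:
they are exactly representable by the RBF layer, so recovering the
planted bump centers is a sharp end-to-end test.  The noiseless signal is
returned alongside for recovery checks, and a generic 2-input benchmark
(`simulate_piecewise_nonlinear`, unit square, plane plus three
sign-alternating bumps) covers the dimension-agnostic core.

What the generator does **not** emulate: serial correlation of treadmill
time series, heteroscedastic sensor noise, HR/MI correlation induced by
exercise stage, subject-level effects, or raw ECG/accelerometer artifacts.
Passing tests therefore demonstrate correctness of the algorithm under the
model's own assumptions, not field accuracy on human data.

## Design choices where the design was open

- "Ten iterations" of the evaluation protocol is read as ten repeated
  random train/test splits with averaged RMSE (not ten clustering
  restarts); exposed as `n_repeats`.
- Contexts condition on the residual only, not on joint input–error
  vectors; the residual is what the correction layer must predict, and
  conditioning the clustering on it is the mechanism that specializes
  prototypes.
- The best grid cell is chosen on *test* RMSE: training RMSE decreases
  almost monotonically with capacity and would always select the largest
  layer.
- Per-unit widths (σ_i) rather than a shared width, matching the
  per-unit subscript of the Gaussian receptive field.

## Known limitations

- Training RMSE is **not** guaranteed monotone in `c` at fixed `p`:
  CFCM re-places all prototypes for each `c`, so the basis sets are not
  nested and a larger layer can land in a slightly worse least-squares
  position (observed, e.g., c=5 vs c=4 on noiseless bump data at one
  seed).  Guaranteed instead: training RMSE ≤ the backbone's for every
  successful fit.
- With large `c × p` relative to the training set, the unregularized LSE
  becomes ill-conditioned and test RMSE can explode; use `ridge`.
- Extreme contexts cover residual tails and may hold very few points;
  large `p` with large `c` on small data fails (by design, loudly).
- The model is not incremental in the online-learning sense: "incremental"
  refers to the architecture (linear model + additive local refinement),
  and refitting is batch.

## Problem sizes used in the shipped checks

Protocol-scale runs use n = 252 samples (the full 4×5 grid with 10
repeated splits completes in a few seconds), recovery checks n = 500,
and the randomized property checks use 20–100 seeded datasets of up to
80 points — sizes at which every documented property is exercised while
the whole suite stays fast.
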