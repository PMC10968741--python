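# Methods

## Signal model and acquisition scheme

The forward model is the two-compartment IVIM representation of the
diffusion-weighted magnitude signal,

    S(b) = S0 · ( f · exp(−D*·b) + (1 − f) · exp(−D·b) ),

with S0 > 0, f ∈ [0, 1], and D, D* ≥ 0 (mm²/s; b in s/mm²). It assumes
mono-exponential decay within each compartment, no exchange between them,
and isotropy: the three orthogonal gradient directions of the reference
protocol are represented as three repeats of the same expectation value,
each receiving independent noise. The default acquisition scheme is the
whole-brain protocol the package evaluates — five b = 0 volumes plus
b ∈ {10, 20, 50, 80, 120, 200, 500, 700, 1000, 1200} s/mm² in three
directions, 35 measurements in all. Measurements are carried in canonical
order (ascending b, repeats contiguous); readers re-sort file input into
this order.

## Noise model

Magnitude MR images are Rician: `S_noised = sqrt((S + N_r)² + N_i²)` with
independent zero-mean Gaussian channel noise of standard deviation σ.
The SNR is referenced to the b = 0 signal, σ = S0 / SNR, constant across
b — matching how scanner SNR is measured in practice (mean/std quotient of
repeated b0 volumes; at high SNR the magnitude noise std equals the channel
σ). Noise is independent per measurement and per realization; no
inter-voxel correlation, non-central-χ multi-coil statistics, or spatially
varying noise fields are simulated. The 36 simulated SNR levels are the
integers 15…50, the only reading consistent with both that count and that
range. Randomness flows from one master seed through per-SNR-level
substreams (`numpy` `SeedSequence` spawn keys), so partial re-runs
reproduce the full run's draws exactly.

## Estimators

All three methods minimize least-squares objectives on the magnitude
signal. Least squares is maximum likelihood under Gaussian residuals; a
Rician-likelihood objective is deliberately not the default (and currently
not implemented) because stage-2 residuals can be negative, where the
Rician density is undefined.

**Segmented grid search.** Stage 1 fits `s0_slow · exp(−d·b)` to the
b > 250 s/mm² subset by exhaustively evaluating a Cartesian (s0, d) grid;
stage 2 subtracts the fitted slow curve from the b < 250 measurements
(b = 0 included — it carries most of the fast-component amplitude) and
grid-fits the residual with `(s0_fast, d_star)`. Negative residuals are
fitted as-is; clipping would bias the fast amplitude upward. Then
`f = s0_fast/(s0_fast + s0_slow)` and `S0 = s0_fast + s0_slow` (f defined
as 0 with a boundary flag if both amplitudes are zero). Ties in the grid
argmin are broken toward the smallest diffusivity, then the smallest
amplitude, for determinism. The vectorized implementation expands the SSE
as `y·y − 2·s0·(E_d·y) + s0²·(E_d·E_d)`; an independently coded residual-form
brute force is kept in the test suite as the oracle and agrees
bit-identically on the selected grid values.

**Segmented curve fit.** The same two-stage decomposition with each stage a
bounded trust-region (`scipy.optimize.least_squares`, `trf`) fit of two
parameters. The default stage 2 fits `(s0_fast, d_star)` on the low-b
residual, mirroring the grid search; an alternative that fits `(f, d_star)`
on the full low-b signal with the stage-1 curve fixed is available via
`stage2="fixed_slow"`.

**One-step curve fit.** A single bounded trust-region fit of all four
parameters, started from the fixed, documented initial point
(S0 = 1, f = 0.1, D* = 0.01, D = 0.001); no data-dependent or random
initialization.

### Split threshold

The 250 s/mm² threshold (configurable) exploits the near-complete decay of
the perfusion component above it — valid when D* ≫ D. For the simulation
ground truth (D* = 0.01) the fast signal at b = 500 is f·e⁻⁵ ≈ 0.8 % of S0
and the approximation is good but not exact: on *noiseless* data the exact
minimizer of the stage-1 objective is displaced from truth by ~0.2 % in D
and the stage-2 estimates by ~2 % in f and D*. This truncation bias is
intrinsic to every segmented method (the grid search hides it below half a
grid step; the one-step fit has none) and grows quickly as D* approaches D:
for tissue-like D* ≈ 0.0036 the fast component retains 41 % of its
amplitude at b = 250, stage 1 absorbs part of it, and f is biased low by
roughly a third. Tests that assert exact noiseless recovery for segmented
methods therefore use scale-separated parameters.

### Grids and bounds

The study this package re-creates does not publish its grid ranges or fit
bounds, and the reported pseudo-diffusion error is strongly range-dependent:
realizations whose stage-2 residual is noise-dominated land on the D* grid
edges, so the upper edge caps the attainable error and directly scales the
D* RMSE. The defaults are the package's own choice:

| axis | range | points | spacing | rationale |
|---|---|---|---|---|
| s0_slow | 0.3 – 1.5 | 121 | linear | brackets normalized S0 with headroom |
| d | 1e−4 – 3e−3 | 117 | linear | brackets human-brain D (0.67–1.2e−3) |
| s0_fast | 0 – 0.6 | 121 | linear | fast amplitude; 0 admits f = 0 |
| d_star | 3e−3 – 3e−2 | 151 | log | brackets reported brain D* fits (3.6–5.2e−3) and the simulation truth 0.01; the upper edge (3× truth) keeps boundary-saturation error at the magnitude seen in vivo |

Curve-fit bounds: S0 ∈ (0, 2], f ∈ [0, 1], D ∈ [1e−5, 5e−3],
D* ∈ [1e−4, 0.15]. The wider curve-fit D* range is why the curve methods
report several-hundred-percent single-voxel D* errors while the grid search
stays near ~90 %: this is a property of the configured search space, not of
the optimizer, and both are fully configurable (YAML `grids:`/`bounds:`
sections). Estimates within 1e−6 relative of a bound (or on a grid edge)
are flagged as boundary hits.

## Monte-Carlo study design

For each SNR level, `n_realizations` noised copies of the *fixed*
ground-truth signal (S0 = 1, f = 0.12, D* = 0.01, D = 0.001 — a
literature-range grey-matter-like voxel) are generated, optionally averaged
in consecutive disjoint groups of 8/27/64 (emulating 2×2×2 … 4×4×4 voxel
pooling), fitted, and reduced to relative RMSE
`100·sqrt(mean((θ̂ − θ)²))/θ` per parameter. RMSE includes non-converged
fits (their best iterates); a converged-only column is emitted alongside.
Each cell carries a delta-method Monte-Carlo standard error so scaled-down
runs are comparable to full-scale ones with honest uncertainty. The
full-scale run uses 17,280 realizations per SNR level (divisible by all
averaging factors); the test suite uses 240–3,456 realizations and the
acceptance script the full 17,280 — the grid-search path is vectorized and
runs the full study cell in seconds, while curve-fit cells scale linearly
with realization count. Realizations are independent, and results are
identical to sequential execution for a given seed regardless of execution
order.

## Volume-level analysis

* **SNR map**: per voxel, mean over sample std (n−1 denominator) of the
  ≥ 2 b0 measurements; zero-variance voxels are undefined (NaN) and
  excluded from summaries. With 5 b0 volumes the sample std underestimates
  σ (c4(5) ≈ 0.94) and the ratio is right-skewed, so the *median* map value
  sits ≈ 9 % above the construction SNR — a property of the estimator as
  used on real scans, reproduced deliberately. `ddof` is exposed.
* **ROI fitting**: each ROI voxel is normalized to its own maximum across
  measurements (absorbing per-voxel intensity scaling), the normalized
  vectors are averaged, and the single averaged vector is fitted.
* **Voxel-wise fitting**: every masked voxel is max-normalized and fitted
  independently; unmasked voxels carry NaN sentinels; failures are flagged,
  never fatal.
* **Classification**: f outliers are "near zero" (f < 0.02, the lower edge
  of the inclusion range, configurable); in-range fractions use the closed
  interval [0.02, 0.25] for f and the half-open [0.006, 0.05) for D*;
  D* boundary hits are counted against the configured search edges.

Tissue segmentation, registration, denoising, and distortion correction are
out of scope: the module consumes label maps produced externally or by the
phantom generator.

## Synthetic phantom

A deterministic nested-shell geometry (CSF core within r < 0.25, GM shell
to r < 0.55, WM to r < 0.9 of the normalized radius; background outside) on
a 1 × 1 × 2 mm grid (affine diag(1, 1, 2, 1)), default 32 × 32 × 16. GM and
WM parameters are in-vivo fitted values (GM: f = 0.09, D* = 0.0036,
D = 0.00065; WM: f = 0.16, D* = 0.00517, D = 0.00079); CSF
(f = 0.05, D* = 0.01, D = 0.003) is a conventional placeholder, as no CSF
fit is reported in the literature the defaults derive from. Optional linear
partial-volume mixing blends compartments within a configurable width of
the shell interfaces. What the phantom does *not* emulate: anatomy, partial
volume beyond linear mixing, spatially correlated noise, and acquisition
artifacts (Gibbs ringing, eddy currents, motion, bias fields) — so passing
phantom tests demonstrates estimator correctness under the model's own
assumptions, not robustness to real-scan confounds.

## Numerical choices and degenerate inputs

* Trust-region fits run with xtol = ftol = gtol = 1e−12, ≤ 400 function
  evaluations; non-convergence returns the best iterate flagged
  `converged=False`.
* At f = 0 the four-parameter model is non-identifiable ({f = 0} and
  {D* = D} fit identically); the one-step fit legitimately stops anywhere
  on that manifold with zero residual.
* All-zero signals drive grid fits to the smallest amplitude grid point
  with boundary flags set.
* bval files are grouped into shells with a chained 1 s/mm² tolerance on
  successive gaps (scanner bval jitter).
* Realization averaging requires divisibility of the realization count by
  the averaging factor and errors out otherwise.

## Known limitations

* The segmented methods' truncation bias (above) means their noiseless
  recovery is percent-level, not exact, whenever D* is within ~an order of
  magnitude of D.
* Reported D* errors are meaningful only relative to the configured search
  range; cross-study comparison of D* RMSE values requires knowing both
  studies' ranges.
* The Rician-likelihood grid objective is reserved but unimplemented.
* In-vivo effects (subject motion, imperfect segmentation, vessel voxels)
  that dominate real-data outlier rates are outside the simulation's scope.
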