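# Methods

## Model

A Bio-FET measurement is a uniformly sampled, dimensionless time series
`X_{t_0}, …, X_{t_M}` with step `Δt`, modeled as a path of the linear
drift-diffusion SDE

    dX_t = [a0(t) + a1(t) X_t] dt + b(t) dW_t,          X(0) = X_0,

with `W_t` standard Brownian motion (`Var[dW] = dt`).  The drift is affine in
the state and the diffusion coefficient is state-independent; state-dependent
diffusion forms (`b(t)X`, `b0(t)X^{b1(t)}`) are excluded because they become
singular or non-real on data that cross zero.  Noise is therefore additive
and Gaussian; no autocorrelation assumption is made.  All computation is
dimensionless; characteristic scales (`char_time`, `char_value`) are applied
only when presenting results next to physical experiments.

## Estimation

The record of M increments is split into disjoint blocks of `2k` increments;
block `j` is centered on increment index `k + 2k·j` and the kernel bandwidth
is `h = Δt·k`, so each kernel's support coincides with (at most) its own
block.  Coefficients are treated as constant per block and assigned to all
member increments.  When `2k` does not divide M the record is extended by
`r` fictitious points (`r` = least nonnegative integer with `2k | M + r`)
lying on the OLS line through the final `2k` observed samples; fictitious
increments participate in estimation only and are discarded afterwards.
This is appropriate for records whose tail is in a steady, nearly linear
regime — the intended regime for saturating binding curves.

Three Epanechnikov variants `(3/(4h))(1 − u²)` weight the increments, with
offset `u = (t_j − t_i)/h`: *left* (support `−1 ≤ u < 0`, strictly
historical), *right* (`0 ≤ u < 1`), *centered* (`|u| ≤ 1`).  One-sided
variants keep their printed mass of 1/2; the constant cancels in both
estimators.

Per window, `(a0, a1)` is the kernel-weighted least-squares fit of the
increment rates `ΔX_j/Δt` on the anchors `X_j`.  The 2×2 normal equations
are solved in anchor-centered coordinates — algebraically identical to the
closed forms, but conditioned independently of how little the window's
anchors move.  If the weighted anchor variance falls below `1e-12` times the
weighted mean square anchor (an unidentifiable slope), the fit falls back to
`a1 = 0` with `a0` the weighted mean rate; fallbacks are logged.

The diffusion estimate per window is the maximizer of the local weighted
Gaussian log-likelihood of the normalized residuals
`E_i = (ΔX_i − [a0(i) + a1(i)X_i]Δt)/√Δt`, in closed form the square root of
the kernel-weighted mean of `E²` (weight sum `S(i)` in the denominator, the
unique stationary point of the likelihood).

A rolling mode (`mode="rolling"`) re-centers the kernel on every increment
instead of using disjoint blocks; it is a diagnostic, not the default, and
one-sided kernels can be degenerate near the record boundary there.

## Reconstruction

Euler–Maruyama stepping with the estimated coefficients:

    Y_{i+1} = Y_i + [a0(i) + a1(i) Y_i] Δt + b(i) ΔW_i,     Y_0 = X_0,

with `ΔW_i ~ N(0, Δt)` from a seeded generator.  The deterministic component
`Y^(d)` uses the same drift on its own state with no noise; the stochastic
component `Y^(w)` is the cumulative sum of `b(i)ΔW_i` (same draws as `Y`),
exposed both per increment and as a path from 0.  When `a1 ≡ 0` the
decomposition `Y = Y^(d) + Y^(w)` is exact.  The drift update always
includes the state factor `a1·Y`; `drift_form="intercept_only"` preserves
the state-free update `(a0 + a1)Δt` for comparison.

## Bandwidth selection

Deviations `A_i = |X_i − Y_i(h)|` over the M+1 samples are summarized by
RMSE (`1/(M+1)` normalization), MAE (`1/(M+1)`), and the deviation standard
deviation (`1/M`), which satisfy `(M+1)·rmse² = M·std² + (M+1)·mae²` exactly
and `mae ≤ rmse`.  The optimal integer multiplier `k*` is found by
exhaustive evaluation of every `k` in the open interval `1 < k < ⌊M/2⌋`
(configurable bounds; no plug-in rules or golden-section shortcuts), one
shared Brownian seed per scan so the scan is deterministic; ties break
toward the smallest `k`, which best honors the piecewise-constant
assumption.  By default deviations are taken against the full stochastic
reconstruction `Y`; `compare_to="deterministic"` scores against `Y^(d)`,
which is seed-independent.  Degenerate windows score `+inf` and are logged,
never silently dropped.

## Cross-validation

For an ensemble of n instruments with optimal multipliers `k*_i`, the
leave-one-out mean `k̄_i` is the average of the other n−1 values, and
consistency is summarized by `|k*_i − k̄_i|` (headline) and
`|k*_i − k̄_i|/k*_i`.  The relative difference is reported but not used to
rank kernels: it rewards a kernel merely for selecting larger multipliers.
The arithmetic stage is a standalone pure function using exact rational
arithmetic, so published bandwidth columns (packaged in
`stochreg.reference`) are checked exactly — e.g. the centered/STD column
gives `k̄_3 = 47/9 = 5.2̄` and `|k̄_3 − k*_3| = 11/9 = 1.2̄` for the third
instrument.

## Synthetic measurements

The experimental trace and the physical solution-well transport model behind
the original ensemble are not deposited.  The generator substitutes a
single-exponential saturating curve `A(1 − exp(−t/τ))` with `τ = tau_ref·ε`,
which honors the one quantitative constraint available: monotone approach to
a plateau, faster for smaller aspect ratio ε (the injected reactant starts
closer to the gate).  I.i.d. Gaussian noise `N(μ_w, σ_w²)` is added to the
samples — measurement noise, not Brownian forcing, and the pipeline is not
told which.  A consequence worth knowing: i.i.d. sample noise makes
successive increments negatively correlated, so the diffusion estimate
recovers `≈ √2·σ_w/√Δt` rather than `σ_w/√Δt`; tests assert only a factor-2
band.  What passing tests on this surrogate do *not* show: recovery of
transport physics, receptor kinetics, or any autocorrelated noise structure
of real instruments.

Defaults, chosen once: `M = 1200`, `Δt = 1`, `A = 1`, `tau_ref = 80`,
`σ_w = 2e-3`, `μ_w = 0`.  With the reference aspect ratios (0.60–4.83) this
gives equilibration times `τ` of 48–386 steps, so every instrument is at or
near plateau within its record, and a noise-to-plateau ratio at which the
optimal objective values are of order `1e-3`–`5e-3`, the magnitude reported
for the experimental instrument.  Ensemble instrument *i* uses seed
`seed + i`.

## Numerical notes and limitations

* Grid uniformity tolerance: `|δt_i − Δt| ≤ 1e-9·Δt`; non-uniform records
  are rejected, not resampled (the windowing presumes uniform Δt).
* Exact pass-through: on noise-free signals whose increment rates are affine
  in the state, the pipeline returns `Y = X` and `b ≡ 0` to machine
  precision whenever every window's design is identifiable and no fictitious
  points leave the affine relation.  That is unconditional for linear
  signals.  For curved (state-dependent) signals two boundary regimes break
  exactness by construction: a left kernel at `k = 2` has a single interior
  support point (slope unidentifiable → fallback), and bandwidths with
  `2k ∤ M` extrapolate the tail linearly, which only approximates a curved
  tail — accurately so once the record is saturated, exactly so never.  The
  test suite checks the exact regimes and treats the rest as approximation.
* Scoring against the stochastic reconstruction `Y` makes every objective a
  function of the scan seed; the deterministic compare mode is provided when
  a seed-free objective is preferred.
* The bandwidth scan cost grows as `O(M² log M)`; the default synthetic
  record (`M = 1200`) keeps a full three-kernel scan to a couple of seconds.
* A master seed derives per-stage seeds by CRC-32 of the stage label masked
  to 31 bits, so ensembles, scans, and reconstructions are independently
  reproducible.
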