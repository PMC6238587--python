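# Methods

## Scope and model

`oxykin` analyses dissolved-oxygen progress curves from Clark-type
electrode assays of sulfhydryl oxidases. The observed consumption rate is
modelled as

    f([O2], t) = x·[O2] + a(t − t_i) · V_max · [O2]^n / ([O2]^n + K_M^n)

with an oxygen-proportional electrode background `x·[O2]` and an enzymatic
term gated by an activation profile `a(τ)` built from sequential
first-order steps (none, one, or two activation steps; optionally a
first-order inactivation following a single activation step, in which case
the intermediate is the active state). Assumptions inherited from this
model family:

* only the terminal activation state (or, with inactivation, the
  intermediate) is catalytically active;
* oxygen binding is described phenomenologically by a Hill curve — the
  package makes no claim about the mechanism behind cooperativity;
* one O2 is consumed per catalytic turnover, so k_cat = V_max / [E];
* the electrode background is proportional to [O2], with the coefficient
  measured per run from the pre-injection phase and held fixed during
  fitting (it can be freed via `fit_background=True`).

Internal units are seconds and μM everywhere; activation/inactivation rate
constants are carried in min⁻¹ and converted internally, k_cat is reported
in s⁻¹ — the units in which these quantities are conventionally tabulated.

## Processing chain

`analyze_trace` applies, in order:

1. **Normalization** (`normalize_trace`). The calibration zero is removed
   by setting the lowest oxygen level to zero. On a noisy trace the
   pointwise sample minimum is an extreme-value statistic biased low by
   ~4 noise sd over 10⁴ samples, which would shift the whole concentration
   axis and visibly bias K_M and the Hill coefficient; the default
   therefore estimates the zero as the mean of the trailing 60 s window
   when that window is statistically flat and sits in the lowest quartile
   of the (10 s smoothed) trace — i.e. when a depleted plateau exists —
   and falls back to the smoothed minimum otherwise. A fixed trailing
   window is used deliberately: any block *selected* relative to the
   minimum inherits its selection bias (measured: ~0.15 μM, worth ~+3% on
   a Hill coefficient of 5). `method="min"` gives the literal pointwise
   minimum; `normalize_method="none"` skips the step for traces already on
   an absolute scale. Both estimators reduce to the exact minimum on
   noise-free data.
2. **Binomial smoothing** (`smooth_binomial`). Convolution with the
   normalized binomial kernel of order 4 (reflection-padded), applied 25
   times by default — an iterated binomial is near-Gaussian with kernel sd
   `sqrt(passes·order/4)` samples, here ≈0.5 s at 0.1 s sampling,
   comparable to the ≈1 s response time of the electrode class itself.
   The heavier-than-minimal default is a deliberate choice: with a single
   pass, 0.5 μM oxygen noise leaves the differentiated trace with ≈1.4 μM/s
   rate noise (S/N < 1 against typical V_max), and residual-randomness
   model selection has essentially no power. 25 passes bring the rate-domain
   S/N to the level at which published differentiated traces are plotted
   and at which a missing cooperativity degree of freedom is reliably
   detected. Smoothing strength does not measurably change the parameter
   estimates themselves (verified at 4/10/25 passes). For noise-free
   oracle data a single pass is appropriate, since smoothing then only
   distorts.
3. **Differentiation** (`differentiate`). Three-point central differences
   (exact for locally quadratic signals), one-sided at the two endpoints;
   the rate is stored consumption-positive. The mask excludes all
   pre-injection points and the first 20 s after injection (mixing
   artifacts); both windows are configurable.
4. **Background estimation** (`estimate_background`). Least-squares slope
   of [O2] over the final 60 s before injection, divided by the mean [O2]
   of that window, clipped at zero.
5. **Fitting and model selection** (below).

## Fitting

`KineticRateRegressor` performs ordinary (unweighted) least squares of the
model rate against the masked (t, [O2], rate) triplets — the estimator
operates on the differentiated data directly, with no error model beyond
homoscedastic noise. Details:

* **Bounds**: rate constants 10⁻⁴–10³ min⁻¹, n ∈ (0.3, 15),
  K_M ∈ (10⁻², 10³) μM, V_max ∈ (10⁻⁶, 10³) μM/s.
* **Degeneracy**: the two-step profile is symmetric under k1 ↔ k2, so the
  fit is parameterised internally as (k1, Δ = k2 − k1 ≥ 0) and reported
  with k1 ≤ k2. When k1 ≈ k2 the individual constants are weakly
  identified; the activation halftime is the stable summary.
* **Starts**: one data-driven start (V_max from a high percentile of the
  smoothed rate, K_M from the oxygen level at half-maximal rate, k1 from
  the half-rise time) plus 8 deterministic Latin-hypercube starts over the
  bounds (log-spaced for scale parameters), seeded by `random_state`; the
  best residual sum of squares wins.
* **t_i**: fixed to the metadata value by default; freed within ±10 s
  automatically if the fixed-t_i fit fails to converge.
* **Uncertainties**: from the Jacobian-based covariance at the optimum
  (σ² (JᵀJ)⁻¹ with σ² = RSS/dof); the k2 standard error is propagated from
  (k1, Δ). No bootstrap by default.
* **Known estimator bias**: nonlinear least squares on a single trace has
  a second-order (curvature) bias that grows with the noise variance; at
  0.5 μM oxygen noise the recovered Hill coefficient runs ≈3–4% high
  (verified to scale with σ² and to be independent of the optimizer and of
  smoothing strength). This is a property of the OLS-on-rate estimator
  itself, not of the implementation, and is left uncorrected; replicate
  means at that noise level recover n within a few percent because small
  opposing systematics (see the simulator's chemical sink) partially
  cancel.

**Residual randomness.** The selection rule is: try candidates
simplest-first (one-step < two-step < one-step + inactivation) and keep
the first whose fit converges with a runs-test p above α = 0.05; if none
qualifies, return the minimum-AIC fit flagged `no-candidate-random`.
`runs_test` itself is the two-sided Wald–Wolfowitz test on residual signs
(normal approximation, zeros dropped). Because smoothing and central
differencing correlate neighbouring residuals — with an anticorrelation
lobe extending to ≈5 kernel sd — the pipeline evaluates it on residuals
thinned to one point per `5.5·kernel sd + 3` samples. Two regions are
tested and Bonferroni-combined: the whole consumption phase (injection to
the first sustained drop of the heavily smoothed rate below 2% of its
peak — the depleted plateau is structureless by construction and only
dilutes the statistic) and the lowest oxygen quartile of that phase, where
a suppressed cooperativity degree of freedom leaves its signature. The
combined statistic holds its ≈5% size on correctly specified fits and
detects a Hill coefficient wrongly clamped to 1 in ≳90% of replicates at
0.2 μM noise.

## Titration analyses

Responses versus substrate concentration (k_cat, activation rate
constants, halftime of activation) are fitted to a single pseudo-first-order
saturating law, `baseline + amplitude·(1 − 2^(−c/midpoint))` for increasing
responses and `baseline + amplitude·2^(−c/midpoint)` for decreasing ones
(direction from the Spearman rank correlation when not given; |ρ| < 0.5
raises a non-monotonicity flag). The law is parameterised by its
half-maximal concentration because that is the only summary independent of
how the exponential is written; comparisons with half-saturation constants
quoted from other parameterisations are approximate. Gel-densitometry band
kinetics (appearance or disappearance of a complex) are fitted to a scaled
two-step sequential profile over a free baseline, with a small
deterministic multistart because the (k1, k2) likelihood of 20-point
densitometry series has a shallow ridge toward one-step-like solutions; at
5% intensity noise the halftime estimator carries ≈8% per-series scatter
and a ≈4% small-sample bias, so accuracy statements are made on replicate
means.

## Forward simulator

`simulate_trace` integrates the model ODE d[O2]/dt = −f([O2], t) (LSODA,
rtol 10⁻⁸, atol 10⁻¹⁰) and emulates the assay as performed: 250 μM
air-saturated buffer (configurable — the true value depends on buffer and
temperature), a 240 s pre-injection phase decaying by background only,
injection of 1 μM enzyme, 0.1 s sampling until well past depletion,
additive i.i.d. Gaussian measurement noise (default sd 0.5 μM) on top of a
constant calibration offset (default 2 μM) that the normalization step
must find and remove, and an oxygen floor at zero.

Two optional nuisance processes make the emulation honest:

* **Chemical background sink** (default 0.002 μM/s, tapering smoothly
  below ≈0.05 μM O2): slow oxygen consumption by the assay mix itself
  (GSH autoxidation and side reactions of the glutathione-reductase/NADPH
  couple; the EDTA in the buffer keeps this to a few μM/h). It is what
  lets traces of highly cooperative enzymes — whose enzymatic rate shuts
  off at a few μM O2 — deplete fully, as real chamber recordings do.
  Without it the normalization has no true zero to find and the recovered
  K_M and n inherit the residual-oxygen offset. The sink is deliberately
  absent from the fitted model; its footprint on recovered parameters at
  the default magnitude is ≈1%.
* **Mixing artifact** (off by default): a transient exponential bump after
  injection, so the 20 s exclusion window has something real to exclude.

A first-order instrument-response filter is not simulated: at the ≈1 s
response time of this electrode class it is negligible against the
kinetics of interest. Features of real data the simulator does not
emulate — electrode drift nonlinearity, temperature excursions, stirring
noise with temporal correlation, enzyme preparations with partial FAD
occupancy — mean that passing recovery tests demonstrates correctness of
the estimators under the model's assumptions, not robustness to every
instrumental pathology.

`simulate_titration` varies V_max and the activation constants across
substrate concentrations by saturating laws (or drives the one-step
halftime directly by a decaying law), recording the generating truth for
recovery tests. `make_fixture_suite` writes four canonical enzymes — the
two-step cooperative Ero1α–PDI type, the one-step Ero1β–PDI type, the
no-lag low-affinity Erv1p type, and a synthetic activation-plus-inactivation
enzyme (its rate constants are plausible placeholders, chosen so the trace
still depletes; no measured values exist for that behaviour) — each
noise-free and at 0.5 μM noise, with a checksummed manifest.

## Numerical choices

* Degenerate limits are evaluated analytically: the two-step profile
  switches to `1 − e^(−kτ)(1 + kτ)` within a relative rate separation of
  10⁻⁷ (likewise the inactivation profile to `kτ·e^(−kτ)`), keeping the
  removable singularity continuous to the order of the genuine first-order
  sensitivity `ε·k·τ²·e^(−kτ)/2`.
* Halftimes use the closed form ln2/k1 for one-step and Brent bisection at
  10⁻⁹ relative tolerance otherwise; inactivation models that never reach
  half-activation raise an error rather than return an extrapolation.
* Integration back-checks (`integrate_model`) clip oxygen at zero and
  enforce monotone non-increase against float wiggle.
* Problem sizes in the test suite: recovery uses 50 replicates per enzyme
  at full trace length (2800 s for the cooperative two-step set, 2400 s
  for the no-lag set, 0.1 s sampling); power/size properties of the runs
  statistic use 8–16 replicates; gel-band accuracy uses 40 replicates of
  20-point series. These sizes put Monte-Carlo error comfortably below the
  tolerances being asserted while keeping the suite around two minutes.

## Limitations

* The package fits the derivative, as the method prescribes; fitting the
  integrated progress curve directly would weight noise differently and is
  not implemented.
* k1 and k2 of a nearly degenerate two-step activation are reported with
  k1 ≤ k2 but are individually soft; confidence intervals on them from the
  Jacobian covariance are optimistic on noisy single traces.
* The runs-test selection rule is parsimonious by design: on two-step data
  whose rate constants are nearly equal it will accept the one-step model
  whenever the lag shapes are statistically indistinguishable — that is
  the stated selection criterion, not a defect, but users comparing rate
  constants across conditions should fix the model structure.
* Oxygen concentrations are taken as already calibrated to μM; the package
  corrects offset, not gain.
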