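# Methods

## Scope and data model

`grazefit` analyses single-prey / single-predator incubation
experiments: a series of containers spanning a geometric progression of
prey densities, each inoculated with the same target predator density,
plus predator-free controls at every few prey levels.  One
`WellObservation` holds the observed initial/final prey and predator
densities (cells mL⁻¹), the raw counted-cell numbers behind them, the
incubation duration, and the diluent (filtered lake water, FLW)
fraction of the container — the main bias covariate.

## Biomass bookkeeping

Cell volume enters either directly (electronic particle counter) or as
a prolate spheroid, V = (π/6)·L·W².  Volume→carbon conversion uses
per-organism allometries C = scale·V^exponent (pg C); the defaults are
0.261·V^0.860 for the cryptophyte prey and 0.216·V^0.939 for the
ciliate predator, i.e. 27 pg C for a 221-µm³ prey cell and 7.00 ng C
for a 63,650-µm³ predator cell.  Internally everything is computed at
full float precision; reporting helpers round to the conventional
precisions (integer pg, two-decimal ng, two significant figures for
mg C L⁻¹).

## Per-well rate estimators

* r = ln(Nt/N0)/t; negative rates are valid, zero counts make the rate
  undefined (an error, not a zero).
* Logarithmic mean density (Xt−X0)/ln(Xt/X0) — the time-average of an
  exponentially changing density; used for both the prey axis ("mean"
  option) and the mean predator density R̄ (a √(R0·Rt) geometric-mean
  option is provided; the two differ by <1% at realistic rates).
* Grazing g = μ_control − ln(Pt/P0)/t.  Because the prey also changes
  in controls, μ_control must be extrapolated across the density axis;
  strategies: `global_mean`, `density_bins` (default, k = 3 equal-count
  log-density bins), `nearest_control`, `interpolate` (linear in ln P).
  The uncorrected variant sets μ ≡ 0.  Negative g (controls declining
  faster than experimental wells) is retained and flagged
  `negative_grazing`, never clamped — the corrected and uncorrected
  datasets are both legitimate analysis branches and the package always
  reports which one produced an estimate.
* Ingestion I = P·g/R̄ with P either the log-mean (default) or the
  initial density; I·m/1000 gives ng C predator⁻¹ d⁻¹.  Clearance
  C = I/P equals the proportion of prey in a 1-mL reference volume
  ingested per day.  GGE = r·M/I_C (carbon) or r·V_pred/(I·V_prey)
  (volume); values outside (0, 1) are flagged.
* Wells with any counted-cell number below 50 are flagged `low_count`
  (the usual counting-precision guideline).

## Response models and fitting

NR: r(P) = rmax(P−P′)/(k₂+(P−P′)), fitted in natural parameters with
bounds rmax ∈ (0, 100], P′ ∈ [0, max P], k₂ > 0.  FR: the generalized
disk equation I = aP^θ/(1+ahP^θ) with θ fixed per candidate (1, 2, or
any user value) or free in [1, 6]; the Michaelis–Menten form is the
same θ = 1 curve and is reported in (Imax, k).  Candidate identifiers:
`NR`, `FR2`, `FR3` (θ=2), `FR3-theta=<x>`, `FR-free-theta`, `FRmm`.

Optimization is trust-region least squares with 8 multi-starts (default)
built from data-driven guesses (max observed rate, density quantiles)
plus seeded log-normal jitter; FR parameters are optimized in log space
to enforce positivity, with tolerances 1e-13 so that noiseless data are
recovered to ≤1e-6 relative error.  Standard errors are linearized
Gauss–Newton (s²(JᵀJ)⁻¹, chain rule back to natural scale); Imax = 1/h
gets a delta-method SE.  The log-transform option minimizes squared
errors of ln I — it removes the variance that grows with prey density
but requires strictly positive ingestion and is therefore only
admissible on the uncorrected dataset; the refusal is explicit.

AICc = n·ln(RSS/n) + 2k + 2k(k+1)/(n−k−1) with k counting the residual
variance (k = n_params + 1), the convention of the standard AICc
tooling.  `rank_models` refuses to compare fits whose response vectors
differ (transform, correction, density axis or n): those likelihoods
are incomparable.  ΔAICc < 2 is labelled "substantial" support.  When
the AICc comparison between a type II and a slightly sigmoidal type III
candidate is inside that band, the decisive diagnostic is the
proportion-ingested polynomial: OLS of C on P and P² (diagonally
rescaled for conditioning, which leaves the t statistics unchanged);
significantly positive linear and significantly negative quadratic
terms ⇒ type III, significantly negative linear without a negative
quadratic ⇒ type II, anything else inconclusive.  α = 0.05 throughout;
weighted OLS is exposed as an option.  The covariate screen fits
μ ~ FLW (controls and experimental separately) and I ~ FLW + R̄ and
reports slopes with p-values; a negative R̄ slope indicates predator
interference.

## Design calculator

Targets follow P_k = P_min·factor^k (recommended factor 1.1–1.5; out-
of-range factors warn but proceed).  Volumes: Dy2 = V·Pini/prey_stock,
Dx = V·Rini/predator_stock, remainder = diluent; modes FLW, FPC
(filtered prey culture — since Dx is constant, Dy2+FPC is automatically
pinned to V−Dx, equalizing the dissolved background), and
predator_filtrate for dilution-sensitive species.  Controls receive an
equal filtered predator volume (Dx_filt) or, optionally, plain diluent
(controls inoculated from predator-free culture) — the latter layout
makes controls systematically FLW-heavier, which matters for the bias
pathology below.  Volumes are snapped to a pipettable increment
(default 0.01 mL) with the diluent absorbing the rounding, so every
container closes to V exactly.  Advisory checks: predator spread >20%,
expected counts <50 cells, factor range, missing controls.  Prey
carried over with the predator inoculum is reported as an additive
density term (off by default).

## The simulator

Each well draws a realized initial density from its target via a
log-normal pipetting ratio whose mean/SD are the study's observed
moments (prey 0.65 ± 0.21 experimental, 0.72 ± 0.17 controls; predator
1.10 ± 0.12 — log-normal because ratios are positive and right-skewed
and only two moments are known).  Prey growth is
μ = μ0 + β_FLW·flw_fraction + ε, ε ~ N(0, σ_μ).  True dynamics are the
coupled ODEs dP/dτ = μP − f(P)·(R/R_ref)^−w·R, dR/dτ = r_NR(P)·R
(controls: dP/dτ = μP, integrated exactly), solved with an adaptive
RK45 at rtol 1e-8 / atol 1e-10; cumulative grazed and grown prey are
integrated alongside, giving a mass-balance ledger accurate to ≤1e-6
relative.  f(P) uses the instantaneous prey density — the log-mean is
an estimator applied afterwards, and that separation is the point:
for θ = 1 with constant predator the closed loop recovers (a, h)
exactly, while for sigmoidal responses the log-mean approximation
leaves a small deterministic residual (~10⁻³ relative) even without
noise.  Observation applies Poisson subsample counting (1-mL prey,
3-mL predator chambers by default).  A lag phase (off by default) is a
hard switch that freezes the dynamics for its duration while the
nominal duration still enters the estimators — reproducing the
rate-underestimation it causes in practice.  Interference uses the
one-parameter Hassell–Varley multiplier (w = 0 by default) because no
quantitative interference form is anchored.

Default generative parameters: NR (0.32 d⁻¹, threshold 1,349 cells
mL⁻¹, k₂ = 10,000 cells mL⁻¹) and FR θ = 3 with Imax = 667 prey d⁻¹
and half-saturation 20,000 cells mL⁻¹.  The two half-saturation-like
constants have no published anchor (the reference fits found them
non-significant); they were chosen once so that ingestion becomes
clearly positive above ~10⁴ and saturates near 4×10⁴ cells mL⁻¹,
matching the qualitative anchors of the motivating study.  Likewise
β_FLW = −0.5 d⁻¹ per unit FLW fraction with μ0 = 0.1 d⁻¹ and
σ_μ = 0.05 d⁻¹ is a synthetic choice (only the sign and significance of
the diluent effect are documented) that reproduces the reported
pathology: FLW-heavier controls decline faster than experimental wells,
producing biologically meaningless negative grazing rates at low prey
density.  Recovery studies that probe estimator noise rather than the
diluent bias set β_FLW = 0 explicitly.

What the simulator does *not* emulate: individual-level stochastic
encounters (demographic noise beyond counting), bacterial background
dynamics, diurnal forcing, nutrient depletion feedbacks, and
physiological state differences between inoculum and culture.  Passing
recovery tests therefore demonstrate correctness of the estimators and
fitting machinery under the modelled noise processes, not robustness of
real experiments to unmodelled biology.

`recovery_study` spawns child seeds deterministically from the master
seed, repeats simulate → derive_rates → fit for each replicate, and
reports AICc win fractions and per-parameter bias/RMSE; failed
replicates are counted and their messages kept.  With log-transformed
fits, non-positive ingestion rates are dropped before fitting (the
all-positive uncorrected dataset is the intended use).

## Problem sizes and numerical choices

The reference layout is 20 experimental wells + 10 controls in 10-mL
containers over 1 d.  The bundled studies use 50–500 replicates:
500 × (30 ODE wells + 2 FR fits) completes in roughly a minute, and the
AICc-instability check uses 100 replicates, enough to bound a win
fraction well away from 0.8.  Ties in AICc ranking are broken by model
id so rankings are order-invariant; perfect (noiseless) fits with
RSS = 0 receive AICc = −∞ rather than an error so identifiability
checks can still rank.  Degenerate inputs raise typed errors
(`UndefinedRateError`, `SingularModelError`, `InfeasibleDesignError`,
`TransformRefusalError`, `IncomparableFitsError`) rather than returning
NaNs silently.

## Known limitations

* No depletion-corrected instantaneous estimators (Rogers/Lambert
  random-predator forms); the log-mean correction is the only depletion
  handling, consistent with common practice.
* Single prey, single predator; no multispecies responses or prey
  switching.
* No temperature/pH/light response surfaces; covariates enter only as
  linear diagnostic screens.
* Confidence bands in plots are pointwise delta-method bands without
  parameter covariances (conservative only when correlations are
  small).
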