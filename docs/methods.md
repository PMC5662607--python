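# Methods

## Model

The package simulates and analyses one-dimensional self-propelled motion of
an animal in a viscous medium at small-to-intermediate Reynolds number,
where drag is linear (Stokes law).  Per unit body mass the equation of
motion is dv/dt = −γv + a(t): γ = c/m combines the whole-body drag
coefficient c and the mass m, and a(t) is the acceleration the animal
exerts in response to environmental cues.  Cues arrive as a Poisson process
with rate ω, so bout durations are exponential with mean 1/ω; within a bout
the acceleration is constant, drawn independently per bout from a zero-mean
distribution with finite variance ν_a².  The forcing is therefore
discontinuous and exponentially correlated (⟨a(t)a(t+s)⟩ = ν_a² e^{−ωs}) —
deliberately *not* a Wiener process.  The animal starts at rest; there is
no thermal-equilibrium initial velocity, which is why the earliest spread
is superballistic (t⁴) rather than ballistic.

Assumptions and scope:

- linear drag only (no Oseen/nonlinear corrections), so results apply to
  small insects, small birds, bats, small fish and similar movers;
- uninterrupted movement (no rest periods); horizontal axis, so gravity and
  buoyancy play no role;
- bout duration and bout acceleration are independent;
- second-moment results are distribution-free in the acceleration law
  (only ν_a² enters); the Gaussian family is the reference case.
- 2D isotropic movement factorises into two independent 1D coordinates,
  ⟨r²⟩ = 2⟨x²⟩; the simulator's two-coordinate consistency test covers it.

## Parameters

| symbol | meaning | units | default in examples |
|---|---|---|---|
| ν_a² | per-bout acceleration variance | length²·time⁻⁴ | 1 |
| ω | cue rate (1/mean bout) | time⁻¹ | 1 |
| γ | drag per unit mass (= c/m) | time⁻¹ | 1 |
| ζ = γ/ω | relative drag intensity | — | spans 4⁻³…4³ |
| η = σ/ω² | length scale (σ = ν_a) | length | 1 |
| τ = ωt | rescaled time | — | — |

All internal analysis is dimensionless in (ζ, η, τ); physical units attach
only at the (m, c) ↔ γ boundary and when converting τ back to t.  The
rescaled diffusion coefficient is η²/ζ², i.e. D = ν_a²/(γ²ω) physically.

The drag taxonomy (effective small-time exponent) is reported with the
convention ζ < 0.1 → low drag (t³), 0.1 ≤ ζ ≤ 10 → intermediate (t⁴),
ζ > 10 → high drag (t²); the continuous quantities τ_sd and τ_d are the
recommended quantitative measures.

## Exact MSD and its evaluation

The closed-form MSD (see README) is valid for all ζ > 0; the derivation's
nominal assumption ζ > 1 is not restrictive — the package treats ζ < 1 as
equally valid, and its Monte Carlo suite confirms the formula across
ζ = 4⁻³…4³ within statistical error.  Numerical care:

- **Removable singularity at ζ = 1.**  The bracket multiplying 1/(ζ−1)
  vanishes at ζ = 1.  For |ζ−1| ≤ 10⁻⁴ (and τ in the float-safe range) the
  code uses the first-order Taylor expansion of bracket/(ζ−1) about ζ = 1,
  with symbolically derived coefficients; continuity at ζ = 1 is verified
  against two-sided evaluation to 10⁻⁸ relative.
- **Cancellation at small τ (and small ζ).**  The result is O(τ⁴) from the
  near-cancellation of O(1/ζ³) terms, so double precision can lose all
  digits.  Every evaluation estimates its own cancellation (machine epsilon
  times the sum of term magnitudes over the result); where fewer than ~11
  digits survive, the value is recomputed with mpmath at 80 significant
  digits (ζ within 10⁻¹² of 1 is offset by 10⁻³⁰ there, equivalent to the
  analytic limit).  Below τ = 10⁻⁸ the curve is returned as its series
  η²τ⁴/4·(1 − (10ζ+4)τ/15).
- **Exponential underflow** to zero (large ζτ or τ) is exact in the limit
  and deliberately permitted.
- The drag-free curve, and the low-/high-drag bracket functions
  (ζτ − 3/2 + 2e^{−ζτ} − e^{−2ζτ}/2 and ωt − 1 + e^{−ωt}), switch to their
  exact power series at small argument for the same reason.

A genuine property worth knowing: the local log-log slope of the exact MSD
at τ = 10⁻⁴ is 4 − (10ζ+4)τ/15, so the measured exponent is 3.9957 at
ζ = 64 — the t⁴ statement is exact only in the τ → 0 limit.

## Transition times

τ_sd(ζ, ε_sd) is the first time the ratio ⟨x²⟩/⟨z²⟩ (exact over drag-free)
falls to the confidence level ε_sd; it is found by geometric bracketing
from τ = 10⁻⁶ and Brent refinement to 10⁻¹⁰ relative.  The closed form
3(1−ε_sd)/(2ζ) is exposed separately.  Its relative error does **not**
vanish as ζ → 0: in the scaling limit τ_sd·ζ converges to the root u* of
3(u − 3/2 + 2e^{−u} − e^{−2u}/2)/u³ = ε_sd, so the approximation
overestimates τ_sd by a ζ-independent factor (5.4% at ε = 0.9, 11.8% at
0.99, 12.4% at 0.999).  The suite grades the approximation at ζ = 10⁻²,
where the deviation is ≤ 2.4%.

τ_d(ζ, ε_d) is the convergence time to the diffusive asymptote
Δ_d²(ζ,τ) = (2η²/ζ²)τ − η²[1+2(1+ζ)²]/(ζ³(1+ζ)).  The exact MSD
approaches Δ_d² *from above* in every drag regime (the slowest-decaying
exponential correction is positive; confirmed against Monte Carlo), so the
defining condition is the proximity equation |⟨x²⟩/Δ_d² − 1| = 1 − ε_d,
solved on the descending branch past the zero of Δ_d².  With this reading
the small-ζ Lambert-W closed form
τ_d ≈ (1/ζ)(3/2 + W[2/(e^{3/2}(1−ε_d))]) matches the exact solver to a few
per mille at ζ ≤ 10⁻², and its error vanishes as ζ → 0.  Δ_d² is negative
at small τ (the asymptote is meaningless there); such values are returned
as-is and the kernel/ratio functions guard against them.

Root uniqueness is not proven; both solvers verify single-crossing on a
diagnostic grid (up to 10× the root for τ_d) and warn if violated.

## Simulator

Within a bout the equation of motion is solved in closed form, so
trajectories are advanced *exactly*: the only error sources are Monte Carlo
noise and ~10⁻¹⁴-level floating-point rounding (expm1-style forms avoid
cancellation at small γ·dt; γ < 10⁻¹² uses the drag-free closed forms).
Observation times truncate the active bout for read-out but never
terminate it — a bout ends only at the next cue.

Ensembles are simulated in fixed-size blocks of 1024 trajectories with
bout matrices sized to cover the horizon (Poisson mean + 6 sd + slack,
topped up in the rare shortfall).  Randomness: every public stochastic
function takes an integer seed; block sub-streams are spawned
deterministically via `numpy.random.SeedSequence`, making ensembles
bit-reproducible.  A single trajectory (`simulate_positions`) consumes its
seed directly.

Histogram estimates of the dispersal kernel use symmetric bins (odd count,
central bin centred at 0 so the renormalised density is exactly 1 there)
covering ±6 standard deviations of Δ_d² (or of the sample when Δ_d² ≤ 0);
a warning is raised when the central bin holds fewer than 10 samples.  The
forcing autocovariance is estimated from one long realisation sampled at 20
points per mean bout, with standard errors from 50 batch means (which
absorb the serial correlation).  The dispersal-kernel reproduction uses
ζ = 1 as its documented default drag setting.

## What the synthetic ensembles do and do not show

All test data are generated by the model itself, at the study conditions:
the drag grid ζ = 4ⁿ (n = −3…3), confidence grids ε_sd ∈ {0.9, 0.99,
0.999} and ε_d ∈ {0.999, 0.99, 0.9}, and unit rescaled parameters.
Ensemble sizes are desk-scale: 10⁵ trajectories for MSD-curve agreement
(4-standard-error bands at ≥ 95% of grid points), 10⁶ displacement samples
for the large-time Gaussianity check (Kolmogorov–Smirnov distance < 0.01 at
τ = 1024), 2–5 × 10⁴ for the remaining statistical checks, with acceptance
bands set accordingly.  Passing these shows internal consistency of theory
and simulation under the model's own assumptions — it says nothing about
real trajectories, which carry measurement noise, behavioural intermittency
(rest periods), heterogeneity between individuals and possibly nonlinear
drag, all outside scope.  Fitting the model to empirical tracking data,
heavy-tailed (infinite-variance) acceleration laws, 3D movement with
gravity/buoyancy, and the full time-dependent dispersal kernel beyond its
Gaussian large-time approximation are likewise out of scope.

## Known limitations

- `msd_exact` is vectorised over τ but scalar in ζ; extended-precision
  fallbacks loop per element (adequate for curve grids and root-finding,
  slow for very large small-τ batches).
- The low-drag MSD approximation carries a generic 3/(2τ) finite-time
  relative error (15% at τ = 10); regime-overlap comparisons need τ of a
  few hundred for percent-level agreement.
- The log-log slope estimator assumes a smooth, strictly positive curve;
  it is not an uncertainty-quantified estimator for noisy empirical MSDs.
- The plotting of curves is left to the user (CSV output is parameter-free
  in σ when η = 1; any figure normalisation is a display choice).
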