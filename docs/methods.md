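# Methods

## The physical model

The package models the horizontal semicircular canal as a circular duct of
centerline radius `r` and cross-section radius `b`, filled with endolymph of
density `ρₑ` and viscosity `μₑ`, containing `N` detached canaliths
(spherical particles of radius `a`, density `ρₛ`) drifting along the canal
at constant speed `ξ̇` from arc position `ξ₀`. A two-turn diagnostic
maneuver — a pitch to angle `α` followed by a roll to the same angle, each
lasting `Δt` — drives the fluid. The observable is the displaced endolymph
volume `Q` (cm³), linked to head kinematics by a first-order lumped ODE

    c(θ₁) Q̇ + θ₂ Q = F(t, α),    Q(0) = 0,

in which `θ₁` and `θ₂` absorb the canal/cupula damping and stiffness. All
quantities are CGS.

Assumptions worth making explicit:

* the duct is rigid and the flow reduces to a single volumetric degree of
  freedom (no Navier–Stokes resolution, no cupula dynamics beyond θ₁/θ₂);
* the canaliths move kinematically (`ξ(t) = ξ₀ + ξ̇ t`, default `ξ₀ = 0`);
  their feedback on the fluid enters only through the drag and gravity
  terms of `F`;
* only the roll turn forces the horizontal canal; the turn kinematics are
  rest-to-rest cubic splines, so angular velocity vanishes at all four
  phase endpoints;
* measurement error on `Q` is additive Gaussian with constant variance, so
  the Fisher information of a design is the weighted sum of sensitivity
  outer products.

### Forcing and its two time-axis readings

The roll-phase spline, written in whole-maneuver time, is
`Ω₂(t) = α(5 − 12t/Δt + 9t²/Δt² − 2t³/Δt³)` with acceleration
`Ω̈₂(t) = 18α/Δt² − 12αt/Δt³`. The forcing is

    F  = Fi + Fn
    Fi = ρ r lₙ sin(Ω₂) Ω̈₂
    Fn = (a²N/b²) [ (4/3) a (ρₛ−ρₑ) ( −r sin α sin(Ω₂) Ω̈₂ − g cos(ξ/r) )
                    + 6 a μₑ ξ̇ ]

(the grouping makes every term a pressure, dyn/cm²). The response integral
runs over `s ∈ [0, Δt]`, but `Ω₂` is a whole-maneuver-time expression, so
two conventions are coherent and both are implemented behind the
`forcing_window` switch:

* **literal** (default): evaluate the expressions at `t = s`. On `[0, Δt]`
  the polynomial sweeps `Ω₂` from `5α` down to `0`, so the integrand
  oscillates for large `α`; this convention treats the printed formulas as
  the definition of the model.
* **shifted**: evaluate at `t = s + Δt`, i.e. on the roll phase proper,
  where `Ω₂` rises from `0` to `α`.

The two conventions give materially different optimal designs; the literal
one is the package default and the one reported by `scripts/acceptance.py`.

### Effective damping and the closed form

The drag contribution proportional to `Q̇` is moved to the left-hand side,
giving the constant effective damping
`c(θ₁) = θ₁ + 6aNμₑ/(πb²(b²−a²))` (≈ θ₁ + 9.7·10⁻⁴ at the defaults). Only
with a constant `c` is the integrating-factor solution

    Q(Δt, α, θ) = e^{−θ₂Δt/c}/c ∫₀^Δt e^{θ₂s/c} F(s, α) ds

exact, and only then are the sensitivities available in closed form:

    f₂ = −(Δt/c) Q + J/c²,      f₁ = −(Q + θ₂ f₂)/c,

with `J = e^{−θ₂Δt/c} ∫₀^Δt s e^{θ₂s/c} F ds` and `dc/dθ₁ = 1`. Both are
validated against central finite differences of `Q` (relative 10⁻³ over a
10×10 grid; typical agreement is far tighter).

## Parameters

| symbol | meaning | default | unit |
|---|---|---|---|
| ρ, ρₛ, ρₑ | canal, particle, endolymph density | 1.0, 2.7, 1.0 | g/cm³ |
| μₑ | endolymph viscosity | 8.5·10⁻³ | dyn·s/cm² |
| g | gravity | 981 | cm/s² |
| A_s | particle frontal area | 3.14·10⁻⁴ | cm² |
| A_s/A_e | particle/canal area ratio | 10⁻⁴ | — |
| r, lₙ | canal circle radius, canalith path | 0.1, 0.5 | cm |
| N | detached canaliths | 6 | — |
| ξ̇, ξ₀ | canalith drift speed, start position | 0.02, 0 | cm/s, cm |
| a, b | particle, duct radius (derived) | ≈0.01, ≈1.0 | cm |
| θ⁰ | nominal damping/stiffness | (0.85, 0.2) | — |

`a = √(A_s/π)` and `b = a/√(A_s/A_e)` are derived but overridable. The
design space is `Δt ∈ [0.5, 1.5]` s, `α ∈ [π/6, π/2]` rad — turns shorter
than half a second or smaller than 30° are not clinically practical — with
the default finite grid `{0.5, 1, 1.5} × {30°, 45°, 60°, 75°, 90°}`.

## Numerical choices

* **Quadrature.** Scalar `Q` and `f` use adaptive Gauss–Kronrod
  (`scipy.integrate.quad`, abs 10⁻¹², rel 10⁻⁹); failures raise with
  diagnostics rather than warn. Grid/batch evaluations use fixed 48-node
  Gauss–Legendre, which matches the adaptive path to ~10⁻¹⁰ (asserted in
  tests) because the integrand is smooth.
* **D-optimal weights (finite grid).** Multiplicative updates
  `wᵢ ← wᵢ·d(zᵢ)/2` from uniform start, run until the maximum generalized
  variance is within 10⁻⁹ of 2; supports below 10⁻⁶ pruned. Deterministic
  by construction; ties between equal-gain points are broken by the fixed
  lexicographic grid order.
* **D-optimal designs (continuous).** Fedorov–Wynn exchange from a 4×4
  start: add the worst violator (multistart L-BFGS-B on the generalized
  variance), re-optimise weights, merge supports closer than 10⁻³ in
  bounds-normalised coordinates. Near convergence the supports and weights
  get a joint log-det polish, aggressive merging (5·10⁻²), and a final
  equivalence re-check at tolerance 10⁻⁶ — the theorem, not the merge
  heuristic, certifies the result. Verification grids use 50×50 samples.
* **Elfving sets.** The symmetrized sensitivity curve is sampled on the
  grid (finite) or 400×400 (continuous; hull area changes <1% on
  refinement, asserted at 60→120 in tests), hulled with Qhull, and rays are
  cut against the facet half-spaces analytically. Cut facets spanned by
  neighbouring curve samples (closer than 10⁻² normalised) collapse to a
  one-point design — the chord-of-a-smooth-arc limit.
* **Direct c-optimiser.** Nelder–Mead over two support points and a
  logit weight with a fixed-seed multistart (exhaustive pair search with a
  golden-section weight solve on finite grids); used as an independent
  cross-check of the Elfving construction (criterion agreement within 1%)
  and never as the primary route. Singular one-point information matrices
  go through a generalized inverse with an explicit estimability (range)
  check that returns +∞ for non-estimable directions instead of raising.
* **Apportionment.** Largest-remainder rounding with every support point
  guaranteed one replicate; ties by index order.
* **Equivalence tolerances.** 10⁻⁶ for optimizer convergence, 5·10⁻³ when
  comparing two-decimal report tables.

## What the verification shows — and does not

The test suite proves internal consistency: spline boundary conditions and
frame orthogonality to machine precision; the closed-form `Q` against a
Runge–Kutta integration of the ODE (relative 10⁻⁶ on a 10×10 grid); the
analytic sensitivities against finite differences; the trace identity
`Σ wᵢ d(zᵢ) = 2`; equivalence-theorem certificates for every returned
design; Elfving-vs-direct agreement. None of this validates the model
against patients: `Q` has never been measured directly, and the link from
displaced volume to observable nystagmus is outside scope. Optimal designs
are local (they depend on the nominal θ⁰); the robustness table quantifies,
but does not remove, that dependence.

Two empirical caveats on the model itself, both documented rather than
patched: the sign claim "stiffness sensitivity f₂ < 0 wherever Q > 0"
holds on the bulk of the rectangle but fails at isolated points where Q is
barely positive (the forcing oscillates in sign); and the Δt → 0 limit of
the response does not vanish under the literal window (the spline
acceleration grows as 1/Δt²) — the zero initial condition refers to the ODE
clock, which is what the generic solver exposes and the tests assert.

## Known limitations

* Two parameters only; the Elfving construction is implemented in 2-D and
  the Carathéodory bound (≤3 support points) is asserted, not configurable.
* One canal, one maneuver shape; no yaw, no >2-phase maneuvers, no
  inter-maneuver dynamics (each maneuver restarts at `Q = 0`).
* The forcing-window ambiguity is exposed, not resolved: the literal and
  shifted conventions disagree, and choosing between them needs data.
* A-, E-, minimax and Bayesian criteria are out of scope.
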