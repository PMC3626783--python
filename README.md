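# vestib-design

Optimal experimental designs for a biomechanical model of the diagnostic
maneuver used in Benign Paroxysmal Positional Vertigo (BPPV).

BPPV is triggered by calcium-carbonate particles (canaliths) that detach
into a semicircular canal of the inner ear; a clinician provokes and reads
the symptoms with a sequence of head turns. This package models a two-turn
maneuver — a positive pitch from upright followed by a positive roll, each
of duration `Δt` seconds sweeping an angle `α` — and computes which
(`Δt`, `α`) maneuvers a clinician should repeat, and how often, to estimate
the canal's mechanical parameters as precisely as possible. It is aimed at
biostatisticians and vestibular-modelling researchers planning such
experiments.

## Model

Each turn is a rest-to-rest cubic spline `Ω(t)` (zero angular velocity at
both ends). The displaced endolymph volume `Q` in the horizontal canal obeys
a first-order linear ODE whose damping and stiffness are lumped into two
unknown parameters `θ = (θ₁, θ₂)`:

    c(θ₁) dQ/dt + θ₂ Q = F(t, α),     Q(0) = 0,

where `F = Fi + Fn` collects the inertial pressure of the head rotation,
`Fi = ρ r lₙ sin(Ω₂) Ω̈₂`, and the canalith drag/gravity interaction `Fn`.
The drag term proportional to `dQ/dt` is absorbed into the constant
effective damping `c(θ₁) = θ₁ + 6aNμₑ/(πb²(b²−a²))`, so the response has
the closed form

    Q(Δt, α, θ) = e^{−θ₂Δt/c}/c · ∫₀^Δt e^{θ₂s/c} F(s, α) ds.

An experiment observes `y = Q(Δt, α, θ) + ε` with Gaussian error. With the
sensitivity vector `f(z) = ∂Q/∂θ` at nominal `θ⁰ = (0.85, 0.2)`, an
approximate design `ξ = {(zᵢ, pᵢ)}` has information matrix
`M(ξ, θ) = Σ pᵢ f(zᵢ) f(zᵢ)ᵀ`, and the package minimises

* **D-criterion** `det M^{−1/2}` — volume of the confidence ellipsoid — by
  a multiplicative algorithm on a finite grid of clinically realistic
  maneuvers (`Δt ∈ {0.5, 1, 1.5}` s, `α ∈ {30°, 45°, 60°, 75°, 90°}`) or
  Fedorov–Wynn exchange on the continuous rectangle `[0.5, 1.5] × [π/6, π/2]`;
  every returned design is verified against the Kiefer–Wolfowitz
  equivalence theorem (`f(z)ᵀ M⁻¹ f(z) ≤ 2` everywhere, with equality on
  the support);
* **c-criterion** `cᵀM⁻¹c` — variance of a parameter combination `cᵀθ` — by
  Elfving's geometric construction: intersect the ray along `c` with the
  boundary of the convex hull of `{f, −f}`; the cut point's generating
  maneuvers are the support and `Φ_c = (‖c‖/‖c*‖)²`, cross-checked by a
  direct two-point numerical minimiser.

Approximate weights are turned into an integer clinic schedule by
largest-remainder apportionment.

## Worked example

```python
import math
from vestib_design import (DesignSpace, d_optimal_finite,
                           generalized_variance, ManeuverPoint)

design = d_optimal_finite(DesignSpace("finite"))
print(design.table(100).to_string(index=False))
z = ManeuverPoint(1.5, math.pi / 3)
print("generalized variance at (1.5 s, 60 deg):",
      round(generalized_variance(z, design), 3))
```

prints

```
 delta_t_s  alpha_rad  alpha_deg  weight  replicates_for_N100
     0.500      0.524     30.000   0.017                    2
     0.500      1.571     90.000   0.494                   49
     1.000      0.524     30.000   0.490                   49
generalized variance at (1.5 s, 60 deg): 0.058
```

Reading: out of 100 diagnostic sessions, 49 should use the 90°/90°
half-second maneuver, 49 the 30°/30° one-second maneuver and 2 the 30°/30°
half-second maneuver. The generalized variance below 2 at a non-support
point confirms D-optimality of the schedule. The same is available from the
shell:

```
vestib-design d-opt --space finite
vestib-design c-opt --c 0,1          # best design for estimating stiffness
vestib-design elfving --plot hull.svg
vestib-design --config cfg.yaml reproduce --out results/
```

`reproduce` writes every design (D- and c-optimal, discrete and continuous),
the generalized-variance and robustness/efficiency tables, and a JSON
summary. All angles are radians internally; degrees appear only in reports.

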