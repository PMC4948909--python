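# Methods

## Model and assumptions

The vessel is an axisymmetric, plane-strain cross-section of three
concentric incompressible hyperelastic annuli (intima, media, adventitia).
Growth is confined to the intima, isotropic in-plane and spatially uniform;
the outer layers neither grow nor atrophy, they only deform elastically to
accommodate intimal expansion.  The morphoelastic split `F = F_e F_g` with
`F_g = diag(g, g, 1)` in the intima and the identity outside, together with
`det F_e = 1` and unit axial stretch, makes the kinematics one-dimensional:
once the deformed lumen radius `a` is known, all interface radii follow in
closed form and the elastic circumferential stretch is

- intima: `α(R) = sqrt(a² + g²(R² − A²)) / (gR)`,
- media/adventitia: `α(R) = sqrt(b² + R² − B²) / R`.

Note that the *elastic* stretch jumps by the factor `g` across the
intima/media interface (the growth tensor switches off there); the
deformation `r(R)` and the total stretch `r/R` are continuous.

Growth at constant volumetric rate `Γ` with equal radial/circumferential
growth stretches integrates to `g(t) = exp(Γt/2)`.  Because growth is
stress-independent, curves of any metric against *stenosis* are invariant
to `Γ`; `Γ` only sets the clock.  For the same reason ex-vivo states can be
produced either by depressurizing each grown state or by growing at `P = 0`
throughout — the two computations are identical, and the test suite asserts
the underlying plaque-area invariance rather than assuming it.

Quasi-statics: growth is slow relative to elastic equilibration, so each
growth level is an independent equilibrium solve with the luminal pressure
held constant.

## Parameters

Moduli in kPa, lengths in mm, time in years, angles in degrees at the API
surface.  Pressure is accepted in mmHg and converted with
1 mmHg = 0.1333224 kPa.  Defaults (a human coronary artery):

| layer | parameters |
|---|---|
| intima | μ₁ = 5 (Neo-Hookean; deliberately compliant — see limitations) |
| media | μ₂ = 1.27, η₂ = 21.60, β₂ = 8.21, φ₂ = 20.61°, ρ₂ = 0.25 |
| adventitia | μ₃ = 7.56, η₃ = 38.57, β₃ = 85.03, φ₃ = 67.0°, ρ₃ = 0.55 |

Reference thicknesses: intima 0.01, media 0.32, adventitia 0.34 mm; the
reference lumen area is free (5–15 mm² is the physiological range used
throughout; 12 mm² is the package default).  Growth rate default
Γ = 0.5 year⁻¹.  The energy convention keeps the printed prefactors
(`ω₁ = μ₁(α² + α⁻² − 2)`, no factor ½); the fiber invariant uses a single
symmetric fiber family per layer, `I₄ = α²cos²φ + sin²φ`.

## Numerics

- **Quadrature**: adaptive Gauss–Kronrod per layer, relative tolerance
  1e-10 — the integrands are smooth.  A 10⁴-point trapezoid oracle exists
  only in the tests.
- **Root-finding**: the pressure balance is solved for `a` by geometric
  bracket expansion around `g·A` (or a warm start from the previous growth
  step) followed by Brent's method to 1e-10 mm.  Monotonicity of the
  residual across the bracket is *vetted*, not assumed: extra roots are
  reported with a warning.
- **Stretch cap**: evaluating the fiber exponential above α = 3 raises a
  diagnostic error (with β₃ = 85 the term overflows long before, and no
  physical configuration gets near it).  The bracketer maps such trial
  states, and overflowing residuals, to +∞ — sign-correct for an
  over-dilated wall — and shrinks the bracket.
- **Spurious-root guard**: far beyond the trusted stenosis range the
  residual develops a second root at lumen compressions `a/(gA) ~ 1e-5`
  with wall stresses ~1e9 kPa.  Genuine late-stage solutions stay above
  `a/(gA) ≈ 0.04`, so the bracketer refuses to descend below 1e-3 and
  reports "no physically meaningful equilibrium" instead.
- **Trajectories**: geometric in `g` (uniform in time), default 400 points
  from 1 to a `g_max` chosen by bisection so the final stenosis reaches
  0.9; the model is not trusted near total occlusion.  The stenosis-target
  search treats a failed solve as "past the target" and backs off.
- **Critical stenosis**: discrete argmax of `L(S)`, accepted as interior
  only if ≥ 2 grid points from either end, then refined by bounded
  golden-section search on a natural cubic-spline interpolant between the
  argmax's neighbours, with a finite-difference concavity check.  A
  shape-preserving (PCHIP) interpolant was rejected here: it cannot
  overshoot data, so its maximum sits exactly on a grid point and biases
  the location by up to half a grid step.
- **Compensation slope**: ordinary least squares of lumen area on plaque
  area restricted to plaque area ≤ 0.5 mm² (configurable; a stenosis-based
  window ≤ 20% is available to mirror the histology convention of
  analysing only mildly stenotic sections).
- **Smoothing spline**: the exact `(k, 1−k)` objective is minimized over
  natural cubic splines with knots at the data sites via the Reinsch /
  Green–Silverman banded system; duplicate stenosis sites are averaged and
  weighted by multiplicity so the original objective is preserved.  `k = 0`
  and `k = 1` are handled as their analytic limits (weighted least-squares
  line; natural interpolant).  No attempt is made to mimic any external
  tool's reparameterization of the smoothing weight — results are
  reproducible from the formula alone (the classic penalized form with
  `λ = (1−k)/k` is used as an independent cross-check in the tests).
- The penalty integral runs over the span of the stenosis values (its
  integrand is `(d²L/dS²)²`, so an integral over lumen values would be
  dimensionally inconsistent).

## Synthetic cohorts

`generate_cohort` emulates the statistical structure of histology/imaging
point clouds, not any published scatter: per vessel it draws a reference
lumen area (uniform 5–15 mm²), a growth rate (log-normal, median
0.5 year⁻¹, ln-sd 0.35 — plaque progression is highly variable between
patients), an observation time (uniform over 0–10 years, which lets
stenoses span roughly 0.05–0.85 at the median growth rate), and, for the
in-vivo preset, a pressure (uniform 50–110 mmHg); it then solves the model
at that state and adds Gaussian noise (σ = 1 mm²) to the lumen area.  The
in-vivo preset discards sections below 10% stenosis, mirroring older
clinical cohorts with essentially no early plaques; draws outside the
stenosis window are re-timed, and a vessel whose growth rate cannot reach
the window within the horizon gets a fresh rate.  All draws flow from one
seeded generator, so cohorts are reproducible.

What passing the recovery tests shows: the spline stage can recover an
interior maximum near the generating curves' mean from 150 noisy,
parameter-heterogeneous samples.  What it does not show: robustness to the
features of real histology the generator omits — eccentric plaques,
measurement bias between modalities, non-uniform sampling over disease
stage, media atrophy, or vasoregulation.

In recovery tests the "recovered" critical stenosis is the median interior
maximum over the moderate-smoothing ladder k ∈ {0.9, 0.99, …, 0.99999}
(mirroring the manual sweep workflow: too little smoothing weight yields a
straight line, too much chases noise wiggles; the emergent location is
stable across the moderate range).

## Problem sizes

Defaults were chosen so a full analysis is interactive on one CPU: 400
equilibrium solves per production trajectory (each a 1-D Brent solve over
three adaptive quadratures, ~40 ms), 150-vessel cohorts, and 100–150-point
trajectories in the test suite, which place the interior maximum to a few
thousandths in stenosis.

## Known limitations

- Axisymmetric, concentric plaque only; real plaques are mostly eccentric.
- Mechanics and growth only: no shear-stress endothelial response,
  vasodilation, media atrophy or other auto-regulation.
- The intima stays a Neo-Hookean solid with time-independent μ₁ = 5 kPa —
  compliant even for healthy tissue — whereas fibrotic intimas stiffen as
  disease progresses.  With this choice the ex-vivo family places the
  critical stenosis near 17–20% (initial-area dependent: ≈ 20.5% at 5 mm²
  down to ≈ 16% at 15 mm²) and the early over-compensation slope at
  ≈ 2.2–2.7 mm²/mm²; a stiffer intima (e.g. μ₁ = 27 kPa) loses both
  behaviors.
- No residual stress / opening angle, no axial pre-stretch, no dynamics.
- Results within ~0.1 of total occlusion are outside the model's trusted
  range and are never reported.
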