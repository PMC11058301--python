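# Methods

## Model

`hemoflow` treats blood in a microvessel as two interpenetrating continua:
Newtonian plasma (density ρ_p = 1027 kg/m³, viscosity μ_p = 0.96 cP) and a
red-blood-cell (RBC) phase (ρ_r = 1093 kg/m³) occupying the local volume
fraction φ (the hematocrit).  Each phase carries its own velocity field;
they share a single hydrodynamic pressure and exchange momentum through
interphase forces.  The governing equations are the phase mass balances

∂_t[(1−φ)ρ_p] + ∇·[(1−φ)ρ_p **v**_p] = 0,  ∂_t(φρ_r) + ∇·(φρ_r **v**_r) = 0,

and the phase momentum balances

(1−φ)ρ_p D**v**_p/Dt = ∇·**T**_p + (1−φ)ρ_p **b**_p + **f**_I,
φρ_r D**v**_r/Dt = ∇·**T**_r + φρ_r **b**_r − **f**_I,

with phase stresses

**T**_p = −p(1−φ)**I** + 2μ_p(1−φ)**D**_p,
**T**_r = −pφ**I** + 2μ_r φ**D**_r     (λ_r = 0 by default, configurable).

The RBC viscosity is shear-thinning and hematocrit dependent,

μ_r = ½[μ_∞ + (μ_0 − μ_∞)(1 + ln(1 + k γ̇))/(1 + k γ̇)](1 + φ),
γ̇ = √(2 tr **D**_r²),

with μ_0(φ) = 537.002φ² + 55.006φ − 0.129 cP, μ_∞(φ) = 27.873φ² − 21.218φ
+ 14.439 cP (viscometric fits for whole blood, interpreted in centipoise),
and k = 11 s.  Two artefacts of these fits matter in practice: μ_0 is
negative below φ ≈ 0.0023 (all evaluated viscosities are therefore floored,
default 0.1 μ_p), and μ_0 < μ_∞ below φ ≈ 0.11, where the law becomes
mildly shear-thickening.  The fit is trusted for φ roughly in [0.05, 0.6];
shear-thinning monotonicity and the bracketing ½μ_∞(1+φ) ≤ μ_r ≤ ½μ_0(1+φ)
hold wherever μ_0 > μ_∞.

The interphase force density is the sum of hindered Stokes drag, Saffman
shear-lift, and spin-lift,

**f**_I = (9μ_p/2a²) f(φ)(**v**_r − **v**_p)
  + (3·6.46 √(ρ_p μ_p)/4πa) φ [2 tr **D**_p²]^(−1/4) **D**_p(**v**_r − **v**_p)
  + (3/4) ρ_p φ (**W**_r − **W**_p)(**v**_r − **v**_p),

with a = 8 μm the RBC size and f(φ) = φ(1 + 6.55φ) the hindrance function.
`a` enters exactly as printed in the source correlations even though the
Stokes prefactor 9μ/2a² conventionally takes a radius; the ambiguity is a
known one and the constant is configurable through `FluidProperties`.  The
tensor products are matrix–vector products; the Saffman prefactor is
regularized by flooring the plasma shear rate (default 10⁻³ s⁻¹), and the
product **D**_p(**v**_r−**v**_p) itself vanishes with **D**_p, so the
regularization only matters at small finite strain rates.  Only the drag is
hindrance-corrected; virtual-mass, Basset and surface-tension forces are
not implemented.  Gravity is available as a uniform body acceleration on
both phases and is enabled (0, −9.81 m/s²) only for the sudden-expansion
benchmark, emulating a horizontal channel; the half-model's symmetry plane
formally conflicts with a transverse body force, which is accepted as part
of reproducing that benchmark's setup.

## Cases

* **Cosine stenosis** (axisymmetric half-domain): wall radius
  y(x) = (H+h_s)/2 − ((H−h_s)/2)·cos(2πx/L_s) for |x| ≤ L_s/2 and H
  outside, with defaults H = 50 μm, h_s = 25 μm, L_s = 70 μm
  (η_h = h_s/H = 0.5, η_L = L_s/H = 1.4) and 500 μm straight entry/exit
  runs.  Uniform axial inlet velocity V_t for both phases, uniform inlet
  hematocrit H_t, zero outlet pressure, no-slip walls for both phases.
* **Sudden expansion** (planar half-domain): 50 μm upstream half-height
  over 1 mm, stepping to 100 μm over 2 mm, V_t = 0.833 m/s, H_t = 20 %,
  transverse gravity.  The printed full heights (100/200 μm) are halved by
  the symmetry model; both readings are configurable.

## Discretization and solution algorithm

Body-fitted structured quadrilateral grids (algebraic transfinite column
mapping; sinh clustering of axial spacing at the throat, uniform transverse
spacing).  Finite volumes are collocated; axisymmetry enters through
radius-weighted face areas and volumes (per radian), which makes the axis
condition metric-enforced, plus explicit hoop terms (the strain-rate
component v/r and the −T_θθ/r momentum source).

The steady state is reached by under-relaxed outer iterations of a
SIMPLE-type loop:

1. Green-Gauss cell gradients with one skewness-correction pass (exact for
   linear fields on the smoothly stretched body-fitted grids used here);
   strain-rate/spin tensors; rheology and lift closures.
2. Phase momentum equations, assembled per velocity component with
   first-order upwind convection (advective form; a minmod-limited TVD
   deferred correction is selectable), over-relaxed orthogonal implicit
   diffusion with explicit cross-diffusion and transpose-stress terms, and
   the phase-intensive pressure force −α∇p.  The drag coupling is implicit
   and the two phases are solved as one 2N×2N block system per component,
   which removes the stiffness of the near-locked phases.  The
   slip-proportional positive-diagonal part of the Saffman term is folded
   into the same implicit coupling.
3. Rhie–Chow momentum interpolation of per-phase face fluxes (the
   pressure-gradient sensitivities come from a per-cell 2×2 elimination of
   the drag coupling) and a pressure-correction equation on mixture
   volumetric continuity, Σ_f[(1−φ)↑ G_p + φ↑ G_r] = 0 with upwinded phase
   fractions; Dirichlet p′ = 0 at the outlet anchors the level.
4. Conservative implicit first-order upwind transport of φ on the
   corrected RBC face fluxes, with local pseudo-time damping, inflow value
   H_t, clipping to [φ_min, φ_max] = [10⁻⁶, 0.68] (clipped volume logged).

**Pressure-term form.**  Taking the divergence of the printed phase
stresses literally gives the conservative −∇(αp) pressure term, whose
p∇φ part is the classic source of non-hyperbolicity of the single-pressure
two-fluid model: implemented that way the iteration limit-cycles (φ
checkerboards near the inlet wall, O(1 m/s) slip at the throat) and never
converges.  The solver therefore uses the phase-intensive form −α∇p — the
standard remedy, and the form production Eulerian–Eulerian codes use — so
that both phases feel the same pressure gradient weighted by their
fraction.  The two forms sum to the same mixture momentum balance.

**Regularization of the dilute RBC limit.**  In strongly depleted zones
(cell-free layers, φ → 10⁻⁴) both the drag (∝ f(φ)) and the RBC viscous
operator (∝ μ_r φ) vanish, leaving an almost force-free, inviscid phantom
phase whose feedback through the φ equation destabilizes the iteration.
Three floors keep this singular limit well-posed, each binding only where
the RBC phase is essentially absent: the α-weighted RBC viscosity in the
momentum operator is floored at 10⁻⁴ Pa·s (the physical μ_r φ at
φ ≈ 0.014), the implicit drag coefficient at 3.5×10⁵ N·s/m⁴ (the drag at
φ ≈ 0.005, making a vanishing RBC phase follow the plasma — the physically
correct limit), and the lift fields are under-relaxed (factor 0.3) between
outer iterations, which is pure iteration damping with no bias at a
converged state.

**Single-phase verification limit.**  With the interphase coupling
disabled and H_t at the φ floor, the RBC continuity equation degenerates
(nothing constrains the divergence of the junk RBC velocity field, so
steady φ transport has no bounded solution on it).  `freeze_phi` pins φ
for these runs and excludes the φ residual from the convergence test; the
plasma equations then carry a uniform (1−φ) factor and reduce exactly to
single-phase Navier–Stokes, which the suite verifies by the invariance of
the plasma field as H_t → 0.

**Convergence.**  L1 residuals are normalized by momentum throughput at
the inlet velocity scale (robust as a component → 0); the volume-fraction
equation converges on its change-based residual, with the conservation
imbalance reported separately — where the packing cap clips, the imbalance
cannot vanish although the iteration reaches a fixed point.  Default
tolerance 10⁻⁶ (10⁻⁵ for the qualitative sweep runs, 10⁻⁷ where discrete
conservation is asserted).  Everything is deterministic: direct sparse
solves, no randomness, bit-identical residual histories on identical
inputs.

## Post-processing definitions

* **Wall shear stress**: magnitude of the tangential component of the
  plasma-phase viscous traction, τ = |(2μ_p(1−φ)**D**_p)·**n** − (…·**n**)**n**|,
  evaluated one-sided from the wall-adjacent cell (a mixture-stress variant
  is available behind a flag).
* **Recirculation extent**: sign changes of the near-wall axial plasma
  velocity (first interior cell row), linearly interpolated.
* **Cell-free / cell-rich layers**: φ < 0.5·H_t and φ > 1.2·H_t.  These
  thresholds are operational definitions of this package — the reference
  descriptions of the regions are verbal/contour-based — and are
  configurable (`LayerThresholds`).

## Problem sizes and study conditions

The shipped studies run at desk scale: stenosis sweeps on 160×20 cells
(velocity sweep; ≈3.4 μm axial spacing at the throat, which is what it
takes to localize the wall-shear peak upstream of the throat at the lowest
inlet velocity) and 120×20 cells (hematocrit sweep; the 10 % case's deep
depletion zones are iteration-stable there), the expansion benchmark on a
64×16 + 140×32 two-block grid (3.1 μm transverse spacing, the coarsest
level that resolves the thin downstream cell-free layer's depletion below
the 0.5·H_t threshold), and verification on up to 200×24.  The
`mesh_independence_study` operation mirrors the refinement procedure one
would run before trusting any of these grids: φ profiles at a fixed
cross-section (x = 20 μm by default, 25 μm selectable) across resolutions
with a pairwise difference table.  Production CFD studies of the same
configuration use ~1.6×10⁵ nodes; field-level agreement with such runs is
out of scope here, and the property/trend suites plus the refinement study
are the substitute instruments.

The run matrices are the study conditions themselves: V_t ∈ {0.1, 0.2,
0.4, 0.8} m/s at H_t = 20 %, and H_t ∈ {10, 20, 40} % at V_t = 0.2 m/s.
The direction of the maximum wall shear stress with H_t is *reported*
(computed: decreasing) but not asserted, because published statements
on it conflict with each other.

## What the desk-scale runs do and do not show

The solver reproduces the qualitative hemodynamics: a downstream
recirculation bubble whose length grows with V_t, a wall-adjacent
cell-free region inside it, RBC accumulation along the straight wall just
beyond reattachment and on the upstream stenosis face, a wall-shear peak
slightly upstream of the throat that grows with V_t, and the
sudden-expansion benchmark's corner eddy with corner RBC accumulation and
downstream cell-free layer.  Quantities tied to thin layers (cell-free
thickness ≈ a few μm) are at the edge of desk-scale resolution and should
be read as indicative; upwind smearing thickens fronts, and the layer
metrics quantify with fixed thresholds what is conventionally judged from
contour plots.  Known limitations: steady flow only (no pulsatility), no
wall compliance, no viscoelastic or thixotropic RBC rheology, no
turbulence, idealized geometries, and the printed lift correlations
applied outside their dilute single-particle derivation range (their
extensional-strain part is treated semi-implicitly for stability but is
physically dubious near stagnation regions).
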