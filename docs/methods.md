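# Methods

## Scope and overall structure

`tendonheal` simulates 20 weeks of Achilles tendon healing as a daily
iteration: mechanics → transport → differentiation → remodeling.  The
simulation state is split between element centroids (tissue densities,
fibril directions, stimuli) and mesh nodes (cell, angiogenesis and oxygen
fields), reflecting that differentiation is a local tissue decision while
transport is a field phenomenon.

## Geometry

The healing construct is an idealized axisymmetric solid of revolution: two
cylindrical stumps (radius 1.0 mm, length 3.0 mm each) joined by a callus
(length 5.0 mm) whose radius follows r(z) = r_s + (R_c − r_s)·sin²(πξ) up to
2.5 mm at mid-length.  Dimensions are order-of-magnitude plausible for a rat
Achilles tendon and fully configurable; they are deliberately generic, not a
reconstruction of any specific animal.  The all-hex mesh maps a structured
square grid onto each circular cross-section with the elliptical grid
mapping x = u√(1−v²/2), y = v√(1−u²/2).  At the default resolution
(8 elements across the diameter, 14 axial) the summed element volume matches
the closed-form profile volume within ~1.3%; the residual is the inscribed
polygon's chord deficit and vanishes with refinement.  Long-horizon test
runs use a coarser 4×8 mesh: the qualitative healing behavior they check is
resolution-independent, and the whole suite stays fast.

## Mechanics engine

The engine is intentionally the simplest model that closes the
mechanobiological feedback loop (densification → stiffening → lower strain →
rule switch): small-strain linear elasticity with, per element,

    C = m · [ C_iso(Ep, ν) + (E1/13) Σᵢ bᵢbᵢᵀ ],

where bᵢ is the Voigt structure vector of fibril direction mᵢ and m is the
tissue-mixture multiplier 0.5ρF + ρT + 2.62ρC + 40.40ρB (floored at 0.01 in
acellular early callus to keep the system nonsingular; stump elements pinned
at 1).  The mixture multiplier scales the full intact parameter set
{E1, E2, K1, K2, Ep, En, Gpn}; the linear engine reads E1 (fibril modulus,
60 MPa), Ep (ground substance, 5 MPa) and ν = 0.3.  These intact moduli are
package defaults chosen so the intact construct sits near 1% axial strain
under the 2 N load and the fresh 10%-density callus spans roughly 5–35% —
the regime in which the differentiation windows are traversed over weeks.
A higher-fidelity (e.g. hyper-visco-poro-elastic) engine can replace this
one behind the same interface.

Loading is a 2 N tensile ramp at 1.1 N/s applied as a consistent uniform
traction on the far face; the near face is clamped (a `roller` mode with
minimal rigid-body constraints exists for analytic verification, where the
single-element bar reproduces F/(A·E_eff) to machine precision).  Stimuli
are evaluated once per day at peak load.  The construct readout is the
secant stiffness, peak force over the consistent-weight mean axial
displacement of the loaded face.

The fluid phase is a one-step backward-difference biphasic solve: the
volumetric strain rate over the ramp (≈1.82 s) sources a Darcy pressure
problem (storage 0.1 MPa⁻¹, permeability 0.01 mm²/(MPa·s)) drained on the
lateral surface; pore pressure is the element mean (compression positive)
and fluid flow is k·|∇p| in μm/s.  These two constants are engine defaults
scaled so pore pressures sit at the 0.1-MPa scale of the PE-PP thresholds.

## Transport

All three species obey dρ/dt = D∇²ρ with backward-Euler steps (dt = 1 day)
on the FE Laplacian with lumped mass — unconditionally stable on coarse
meshes and exactly mass-conserving without sources.  The external callus
surface is the Dirichlet-1 source for all species (extrinsic healing
compartment); stump-interior nodes are native vascularized tissue held at 1
for angiogenesis and oxygen, while for cells they are an initial condition
only (infiltration is extrinsic).

- **Cells.**  The diffusivity D is calibrated by bisection so the
  volume-weighted mean callus cell density reaches 95% at day 14
  (≈0.11 mm²/day on the default mesh).  The calibration is monotone in D
  and returns the upper bracket end, so a replay lands in [95%, 95%+ε).
- **Angiogenesis.**  Diffusion is assembled only over elements whose
  octahedral shear strain is below the A-OSS threshold (default 6%, the
  middle of the 3–6–12% sensitivity grid); fully gated neighborhoods do not
  evolve, and the field is kept non-decreasing (vessels do not regress).  A
  node strictly above 90% angiogenesis becomes a matured vessel: a monotone
  blood-supply flag and a new oxygen source.
- **Oxygen.**  dρ/dt = O∇²ρ − C·ρ_cells·ρ with C = 0.5/day.  The sink is
  integrated exactly by operator splitting (implicit diffusion step, then an
  exponential decay factor), so an isolated fully cellularized node decays
  as e^(−Ct); splitting also guarantees oxygen with consumption is pointwise
  bounded by oxygen without.

**Units of A and O.**  Only relative factors (0.25–0.5–1.0) are physically
specified for the angiogenesis and oxygen diffusivities, so the package
anchors them as A·(vascular_ratio·D) and O·(vascular_ratio·D) with
vascular_ratio = 0.125.  The ratio encodes that capillary ingrowth and
blood-borne oxygen delivery are far slower than interstitial cell migration:
cells fill the callus in two weeks, whereas vascularization and core
re-oxygenation span most of the 20-week horizon.  At this anchor the callus
core is hypoxic (<3% oxygen) for weeks while the periphery is perfused —
the regime the oxygen-coupled rule set is built around.  Anchoring at the
cellular scale instead oxygenates the core within days and collapses the
oxygen framework onto the plain strain rules.

## Differentiation

Rule sets are data: ordered, mutually exclusive conjunctions of interval
predicates with tendon as the universal fallback (the fibrous-tissue outcome
of the bone-regeneration schemes plays the tendon role).  Boundary ties are
closed on the cartilage side (ε₁ = 2% or 4% → cartilage; stim = 1 or 3 →
cartilage).  Compressive thresholds compare compressive magnitude: the PE-HS
cartilage branch uses max(0, −σ_h), the PE-PP bone branch uses |PP|.  In
PE-OXY, hypoxia (oxygen < 3%) takes precedence over the vascular strain
rules — hypoxic chondrogenesis is the mechanism the scheme encodes — and
sites that are neither hypoxic nor vascularized produce nothing; an element
counts as vascularized when any of its nodes is a matured vessel.
A randomized coverage check (exclusivity over generous stimulus ranges) runs
at simulation start and in `rules validate`.

The endochondral gate (PE-ENDO) blocks bone proposals unless ε₁ < 2% and
either ρC exceeds the scaffold threshold (20% or 25%) or ρB > 0; a blocked
proposal means no production that day for that element.

The tendon production law rises linearly from 0 at 0% strain to the default
rate (2%/day) at 15% and falls linearly to 0 at 30%: over-strained tissue
produces nothing.  The breakpoints and peak are configurable; the shape is a
minimal continuous realization of "production increases with strain up to
15%, then decreases".  The strain law applies to tendon in PE, PE-ENDO and
PE-OXY; the older schemes (PE-HS, PE-PP, OSS-FF) use the constant default
rate, and cartilage/fat/bone use 2%/0.02 and 1.2%/day respectively.

## Remodeling

The produced tissue gains Δ = rate·ρ_cells·dt; the other three tissues
jointly lose min(Δ, their total), apportioned proportionally to their
current densities — a choice that preserves relative composition (the split
is otherwise unconstrained).  The target gain is clamped so no density
leaves [0, 1] and the total never exceeds 1.  Days 1–5 are an inflammatory
phase: tendon forms at 50% of the default rate independent of stimuli, and
no mechanoregulated production runs in parallel.  Stump elements are
immutable (ρT = 1, fibrils axial).

Fibrils (13 per element, initialized uniformly on the sphere from the run
seed) rotate toward the current maximum-principal-strain direction in the
plane they span with it, by a fixed daily angle equal to their day-0
reference angle over 28 days (capped at the remaining angle), so alignment
completes in four weeks from any start; the update is sign-symmetric and
rotation-equivariant.

## Daily loop and determinism

Within a day: mechanics solve → cell step → (PE-OXY only) gated angiogenesis,
vessel maturation, oxygen step → classification (+ endochondral gate) →
production/degradation → fibril reorientation → recording.  The same day's
stimuli gate that day's angiogenesis.  The RNG is consumed only by fibril
initialization, so runs are bit-identical for a fixed config and seed.  The
parameter sweep is one-factor-at-a-time from the base config with a shared
seed and a single shared infiltration calibration.

First-appearance days are measured as the first day a tissue's mean callus
density rises 0.1 percentage points above its initial value (tendon starts
at 10%, so an absolute threshold would misreport it as present at day 0).

## What the synthetic conditions do and do not show

All inputs are generated internally: the idealized geometry, the default
load protocol and the printed rates/thresholds are the study conditions.
Passing tests demonstrate that the implemented mechanisms interact as
described — tendon before cartilage before bone under PE, less bone and
persistent cartilage under the endochondral gate, core-centered cartilage
and hypoxia-sensitive chondrogenesis under PE-OXY — on a generic construct.
They do not validate absolute magnitudes (stiffness in N/mm, bone volume in
mm³) against any animal, because the engine is linear, the geometry is
idealized and the intact moduli are package defaults.  Degradation kinetics
of fat and whether consumption saturates at high cell density are untested
model choices (the linear sink is implemented as printed).

## Known limitations

- Linear small-strain engine: no viscoelasticity, finite strain, or
  tension–compression asymmetry; secant and tangent stiffness coincide.
- Continuum tissue fields cannot represent the discrete, unconnected
  ossification islands seen histologically.
- Hex-only meshing; no remeshing or stump–callus contact.
- Transport uses a single implicit step per day; sub-daily dynamics and
  discrete vessel networks are out of scope.
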