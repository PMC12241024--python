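# Methods

## The physical problem

A circular stapler clamps two annular layers of intestinal wall between a
rigid anvil (above the "upper" layer) and a rigid staple cartridge (below
the "lower" layer). The anvil advances in 0.1 mm steps up to 80% of the
total undeformed thickness `t_u + t_l`; the question is which steps leave
the tissue *fixed but undamaged*. Thickness pairs studied by default:
2.5–2.5, 2.0–2.0, 1.5–1.5, 2.5–1.5 and 1.5–2.5 mm, spanning reported
colonic, rectal and ileal wall thicknesses.

## Constitutive model

Incompressible Ogden solid,
`W = Σ_p (μ_p/α_p)(λ₁^α_p + λ₂^α_p + λ₃^α_p − 3)`, in the μ/α convention
of the major commercial FE solvers. This convention choice matters: with
the shipped constants (μ = 8300/200/6200 Pa, α = 7.625/13.875/7.625,
initial shear modulus μ₀ = ½Σμ_pα_p ≈ 56.7 kPa) the uniaxial stress at
60% compression is ≈ 0.59 MPa, just inside the 0.6 MPa damage threshold —
which is exactly what makes a 60% safe ratio possible. The alternative
`2μ/α²` normalisation would place that stress elsewhere and contradict
the safety tabulation, so it is not offered. Two of the three terms share
α = 7.625; they are kept verbatim, not merged. All lengths are mm and
stresses MPa internally; configuration accepts the constants in Pa.

The FE engine enforces near-incompressibility with an isochoric split
(λ̄ᵢ = J^(−1/3)λᵢ) plus a volumetric penalty `(K/2)(J−1)²`. The default
penalty is `K = 5·10⁴ μ₀` (≈ 2.8 GPa): stresses near 80% nominal
compression reach tens of MPa, and a much softer penalty would let the
volume drift by several percent and visibly perturb the deviatoric
response through λ̄. With this value the global volume error stays below
~0.3% in the verification runs and the deviatoric deviation from the
exactly incompressible closed form is ≲ 0.25%.

## Safety statistic

Per layer and step, element volumes are summed into three exhaustive
bands of centroid von Mises stress: (0.1, 0.3), [0.3, 0.6] and
(0.6, ∞) MPa. Membership uses the *current* (deformed) element volume —
Cauchy stress pairs naturally with deformed volume; a reference-volume
variant is available by constructing results with reference volumes. The
boundary conventions (0.3 and 0.6 inclusive in the fixation band, damage
strictly above 0.6, fixed tissue strictly above 0.1) make the three
defining phrases mutually exclusive and exhaustive. A layer is safe iff
the fixation fraction strictly exceeds 0.20 **and** the damage fraction
does not exceed 0.05 of the fixed-tissue volume. When nothing exceeds
0.1 MPa the layer is reported as an explicit "no fixation" state, never
as a 0/0 fraction.

Compression ratios are printed at two decimals computed in exact decimal
arithmetic on tenths of millimetres with half-up rounding: binary floating
point would render 2.3/4.0 = 0.57499… and round to 0.57 instead of the
correct 0.58. Safe ranges are reported as discrete step sets (the grid the
load program actually visits), not interpolated intervals.

A note on monotonicity: "raising every element's stress can never rescue a
damaged layer" holds only when no new volume crosses the 0.1 MPa
fixed-tissue floor; otherwise the growing denominator can dilute the
damage fraction below 5%. The property test therefore asserts it on
fields already entirely above the floor, where it provably holds.

## Engines

**Uniform engine.** Full-contact, laterally free, homogeneous
incompressible uniaxial compression: λ_z = 1 − d/(t_u+t_l), stress from
the closed form, both layers identical by series equilibrium, reaction
force = |σ|·(anvil effective area). It is exact for its configuration,
runs in milliseconds, and drives the safety tabulation.

**Axisymmetric FE engine.** 4-node quadrilateral ring elements on a
structured mesh (z = compression axis, r = radial; the layer interface is
a shared node row, i.e. bonded tissue–tissue contact). Total-Lagrangian
kinematics; principal stretches from the in-plane stretch tensor plus the
hoop stretch; mean-dilatation treatment of the penalty term (element-mean
J in the pressure) to prevent volumetric locking. Element tangents are
formed by central finite differences of the exact element force vector
(vectorised over all elements; verified against a global FD Jacobian to
1e−9 relative), so the Newton direction is consistent including the
mean-dilatation and spring-tie couplings.

Boundary conditions follow the physical setup: outer tissue surface fixed
radially and free axially; nodes under full-contact anvil bands move
rigidly with the platen; nodes under cartridge bands are held fixed;
bands with area fraction < 1 are tied through penalty springs scaled by
the fraction of nodal tributary area in true contact (stiffness
`2K/element_size` per unit area — ~10⁵× the tissue stiffness, slip below
1e−3 mm). The cutting washer is merged into the anvil platen, which the
load program moves as one body. A `frictionless` mode (axial constraints
only, lateral surfaces free) reproduces the uniform engine's homogeneous
solution and anchors the verification suite.

Newton globalisation, in escalation order: a first-order continuation
predictor (solve `K Δu = −∂R/∂d Δd` at the converged state — essential,
because a naive predictor concentrates the increment near the platen and
the stiff penalty then dwarfs the Newton basin); backtracking line search
with a half-element trust cap; a penalty-continuation ladder
(K/250 → K/25 → K) restoring the solution branch when the direct solve
fails; and finally step bisection (3 levels). A step that still fails
raises a structured error naming the step; the thickness sweep records
such failures per pair and continues.

## Contact-surface surrogate

The true device contact surfaces are proprietary, so they are reduced to
axisymmetric annular *footprints* on a tissue annulus of r = 10–16 mm
(34 mm-class device; configurable). Two facts about this reduction were
learned the hard way and shape the defaults:

1. **The tissue must out-span the lands.** With the outer surface held
   radially, an incompressible annulus whose whole top face is tied cannot
   compress past ratio `(r_o²−r_i²)/r_o²` ≈ 0.39 — the volume has nowhere
   to go. Real tissue extends beyond the device lands; the default
   footprints leave free rim tissue inside and outside.
2. **Relief must be distributed.** A wide no-slip land over nearly
   incompressible tissue builds squeeze-film pressure like (width/gap)².
   The real faces are perforated by staple holes, forming pockets and the
   cutting clearance at millimetre pitch. The surrogate therefore uses
   three narrow lands per face with gaps between them; the cartridge lands
   are narrower and carry area fraction 0.8, giving a cartridge/anvil
   effective-area ratio of 0.575 and reproducing the mechanism that the
   cartridge-side (lower) tissue sees the harsher stress state.

Within its regime (compression ratios up to ~0.35 on the default
geometry) the bonded surrogate shows lower-layer maximum stress ≥
upper-layer maximum at every step past 20% compression, layer mean
stresses tracking within 20%, global volume drift ≤ 2%, and monotone
force–displacement. Beyond that the 2-D annular gaps exaggerate the
extrusion that 3-D holes distribute, layer means diverge, and past ~50%
elements at band edges distort until the solver reports the structured
failure; the uniform engine (whose stress state matches the safety
tabulation's assumptions) covers the full 80% program.

## Experiments

* **Thickness sweep** — the full load program per thickness pair; emits
  per-step layer statistics, band-fraction series and the safety table.
  Deterministic given its configuration. Default engine: uniform.
* **Mesh convergence** — ladder of element sizes (default 2.0→0.4 mm);
  the monitored quantity is the volume-weighted mean von Mises stress of
  the whole tissue (the element maximum is singular at footprint edges
  and cannot converge). Selected size: first whose change from the
  previous is < 3%; a never-converging ladder returns the smallest size
  flagged. The test suite monitors at 30% compression of the 2.0–2.0 mm
  stack, the regime the bonded surrogate resolves cleanly.
* **Validation curve** — model force at the compression ratios of a
  reference force curve, on a grid ending where the platen gap reaches
  1 mm. The contract is two-regime: within an order of magnitude
  everywhere, within a factor of two below 60% compression. Since the
  original bench data are not published, the shipped reference is
  *synthetic*: the closed-form curve under seeded multiplicative
  log-normal noise (σ_log ∈ [0, 0.5], default 0.15) — positive by
  construction, bit-reproducible from the seed, and recorded with full
  provenance. Passing validation against it demonstrates pipeline
  correctness and noise tolerance, not agreement with any real tissue
  measurement.

## What the synthetic data do and do not show

The generators emulate the *shape* of the study inputs: geometry presets,
a plausibly noisy reference force curve, and band-classifier fixtures.
They do not emulate biological variability (oedema, fat content,
perfusion), rate dependence (the model is quasi-static), frictional slip
(contact is bonded), or the true PYGX-34 hole pattern. Tests passing on
these fixtures verify the mathematics and the software contract, not
clinical applicability.

## Numerical choices and limitations

* Newton tolerance: residual ≤ 1e−6 × the constraint-force norm (+1e−9 N
  absolute); stress at element centroids; current volume = reference ×
  det F at the centroid.
* Structured quad meshes only; at least two element rows per layer;
  element size must not exceed the thinner layer.
* The FE mesh volume identity Σ2πr̄A = analytic annulus volume is exact
  for rectangular cells, so the 0.5% mesh-volume guard only triggers on
  genuinely corrupt geometry.
* Reported deterministically: identical configuration ⇒ byte-identical
  CSV/VTK/manifest outputs (fixed float formats, ordered fields).
* Unilateral contact outside the bonded bands is not modelled: at extreme
  compression tissue may interpenetrate the platen plane between lands.
  Staple forming, cutting, compression-rate effects and 3-D hole
  geometry are out of scope.
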