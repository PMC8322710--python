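# Methods

`oculotamp` models the mechanics of a silicone-oil (SiO) tamponade in a
vitrectomized eye at two levels: the *static* oil–aqueous equilibrium, which
determines how much of the retina the tamponade actually touches in a given
head posture, and the *dynamic* wall shear exerted on the retina during a
saccade. Both are reduced-order models: no volume-of-fluid Navier–Stokes
solve is involved, and the package makes no claim to reproduce pointwise CFD
fields — only the geometric contact quantities, the closed-form–checkable
kinematics, and the order-of-magnitude and ordering structure of the shear
response.

## Geometry

The vitreous chamber is a sphere of radius `eye_radius` (default 12 mm)
indented anteriorly by the posterior surface of the crystalline lens,
modeled as a second sphere (`lens_radius` = 5.5 mm, center
`lens_center_offset` = 13 mm along the anterior axis; rim at ≈25° polar
angle). These lens parameters are configurable defaults chosen to place a
phakic lens qualitatively in the anterior cap; the enclosed volume is then
≈7035 mm³ versus 7238 mm³ for the bare sphere. The surface is a subdivided
icosphere whose vertices inside the rim cone are radially projected onto the
lens sphere, so the mesh is watertight by construction and the chamber is
star-shaped about the eye center — the property every volume quadrature
below relies on. Default target edge length: 0.45 mm (10 242 vertices).

Anatomical frame: anterior = +z, superior = +y, nasal = +x, fixed to the
eye. Wall regions by polar angle ψ from the anterior axis: lens (ψ ≤ rim),
ora band (rim < ψ ≤ 40°), pre-equatorial (40° < ψ ≤ 90°), post-equatorial
(90° < ψ < 160°), macula (ψ ≥ 160°, i.e. a 20° cap on the posterior pole).
The 40° ora limit is a configurable convention; the ora band and lens are
*excluded* from every "retina" denominator, which aggregates macula +
post- + pre-equatorial. Hemispheres split on the sign of the superior
coordinate (anatomical split, independent of gravity); points exactly on
the dividing plane are tie-broken by the nasal coordinate so symmetric
bands split evenly.

Region and wetted areas are accumulated by barycentric splitting: each face
is subdivided into 4^depth equal sub-triangles (depth 2 by default) whose
centroids are classified against the analytic cone boundaries or the solved
interface. This conserves total area exactly and converges as 4^-depth;
plain per-triangle majority voting was measured too coarse (≈2.6% macula
error at 1 mm resolution) and too noisy for the energy landscape below.

## Static equilibrium

Fluids (SiO1000/SiO5000 vs aqueous): oil density 980 kg/m³, aqueous
1000 kg/m³, interfacial tension σ = 0.044 N/m, static contact angle 16.2°
(advancing 21.2°, receding 11.2°). The contact angle is interpreted as
measured **through the aqueous phase** — the aqueous wets the retina — with
a convention flag to flip. Equilibrium is viscosity-independent, so one
solve per (posture, fill) serves both oil grades. Postures map to gravity
directions in the anatomical frame: standing → −superior, supine →
−anterior, 45° upward gaze → the unit bisector.

The capillary length √(σ/Δρg) ≈ 15 mm exceeds the eye radius
(Bond number Δρ·g·R²/σ ≈ 0.64), so surface tension is *not* a small
correction here; a flat interface is a poor approximation at these scales.

The interface is restricted to a two-member family: planes normal to
gravity, and spheres with center on the gravity line through the chamber
centroid (signed curvature κ; κ = 0 is the plane). For each κ the volume
constraint (oil volume = fill × chamber volume) is solved by root
bracketing along the gravity line, and the winning member minimizes

    E = σ·A_interface + σ·cosθ·A_wall,oil − Δρ·g·∫ z dV_oil,

with z the height along the anti-gravity direction. The family is exact in
the zero-Bond limit (spherical cap) and the infinite-Bond limit (flat
stratification); at Bo ≈ 0.64 the minimizer interpolates. Two physical
side-conditions prune the family:

* **Contact-line admissibility.** The apparent contact angle where the
  interface meets the eye sphere (uniform along the contact circle for any
  plane or sphere) must not fall below the static angle: an over-wetted
  contact line would spontaneously advance, so such members — which form a
  near-degenerate valley of "thin-film" configurations, since
  cos 16.2° ≈ 0.96 makes wall energy and interface energy almost
  interchangeable — are not static equilibria. The lens contact line is not
  constrained.
* **Buoyant stability.** The uppermost chamber point must be on the oil
  side. Without this, the lens geometry admits an *inverted* minimizer at
  some supine fills (pooling the oil posteriorly avoids wetting the
  high-area lens recess at an energy saving comparable to the gravity
  cost); inverted stratification is Rayleigh–Taylor unstable and
  unreachable from the surgical filling process.

Numerics: volumes and height moments come from exact per-ray integration
over the star-shaped chamber (one ray per face; planes use an exact
divergence-theorem polyhedral integral instead, because rays lying in the
interface plane would make the radial quadrature discontinuous in the
offset). Interface areas use a deterministic column quadrature with
bisection-refined chamber crossings (error ≪ 1 mm²; plain point sampling
was measured to corrupt the ~10⁻⁶ J energy differences that separate
neighboring members). The outer κ search is a 45-point scan over
|κ| ≤ 1/(0.25·R) with two staged grid refinements; volume tolerance 10⁻⁴
of the chamber volume.

The **supine analytic oracle** (`analytic_supine_coverage`) is the same
energy principle restricted to the axisymmetric lens-free case and
evaluated entirely from spherical-cap closed forms (wall cap + meniscus
cap), with the same admissibility rule; with the contact-angle term
disabled it reduces to the flat-interface cubic x²(3−x) = 4·fill, coverage
x/2. It shares no code path with the mesh solver — no mesh, no quadrature —
and the two agree to within 0.8 percentage points over fills 80–95%.
A note on the Young condition: a spherical meniscus through a contact
circle at polar angle β can only meet the container at angles ≥ |90°−β|,
so for small aqueous pockets the exact Young angle is geometrically
unattainable within this family; constrained energy minimization is the
consistent formulation.

Known limitation: forcing a single curvature onto the whole interface
exaggerates capillary dewetting relative to a true constant-mean-curvature
surface (which would flatten centrally under gravity and curve only near
the wall). The model therefore under-predicts total retina contact at low
fills compared to full two-phase CFD — by roughly ten percentage points at
80% fill — while matching the per-sector structure (inferior hemiretina,
inferior pre-equatorial sector, macula coverage pattern) well at 90% fill.
The standing-posture annular aqueous rise between lens and ora is
reproduced only insofar as the spherical family allows; no explicit
annular-meniscus correction is applied.

## Saccade kinematics

The angular displacement is a quintic polynomial θ(t) = Σ cᵢtⁱ on
[0, T] with T = 0.137 s and published-style coefficients c₀ = c₁ = 0,
c₂ = 2.01×10⁴, c₃ = −3.29×10⁵, c₄ = 2.30×10⁶ (degrees, seconds). The
quintic coefficient is not part of that set; it is recovered from the
end-rest condition dθ/dt(T) = 0, giving c₅ ≈ −6.04×10⁶ °/s⁵. The resulting
amplitude is 50.01° (printed value 50°, the alternative of fixing c₅ by
amplitude differs below reporting precision) with peak angular velocity
547.1 °/s at 34.5 ms. The eye is then held fixed for a second window of
length T to observe the fluid's deceleration. Rotation axis: the
superior–inferior axis by default (horizontal saccade) — the source
kinematics do not state it — configurable.

## Saccadic wall shear

Each wall vertex is treated as a flat plate moving with the local wall
speed U(x,t) = ω(t)·d(x) (d = distance to the rotation axis) beneath a
semi-infinite layer of the locally contacting fluid, frozen from the
equilibrium wet map (oil where wet, aqueous where dry; the interface does
not deform during the saccade). The wall traction is the Duhamel
superposition over the Rayleigh step response,

    τ(t) = √(ρμ/π) ∫₀ᵗ U′(s) (t−s)^{−1/2} ds,

evaluated by product integration that treats the (t−s)^{−1/2} endpoint
singularity exactly on each step (piecewise-linear U). Validity: the
viscous penetration depth over one saccade, √(νT) ≈ 0.37 mm for SiO1000
(0.84 mm for SiO5000), is small against the 12 mm chamber, which justifies
the half-space idealization; a finite-gap variant (implicit 1-D diffusion
across the distance to the rotation axis, stress-free far side) is provided
for sensitivity checks. Because U is separable, one convolution of the
angular-velocity history serves every vertex. Default time step 1 ms over
[0, 2T] (275 samples); halving the step changes peak traction by <1%.

Structural consequences, all exact in this model: traction scales as
√(ρμ), so SiO5000/SiO1000 = √5 ≈ 2.24 pointwise (the CFD analogue is
"almost twice"); traction histories are bimodal (acceleration peak near
onset, deceleration peak at the stop, a same-signed inertial tail after);
aqueous-wetted wall sees √(1000)-fold smaller stress than oil-wetted wall
at equal kinematics. Retinal peak stresses land in the tens of pascals for
SiO5000 at 90% fill — the right decade, with no claim of pointwise CFD
accuracy. What the model *cannot* produce: meniscus-line stress
concentrations (the contact line is not specially modeled), secondary
(meridional) flows, and any nonzero vertical-average pattern from 3-D
effects.

## Shear metrics

For a traction series, five summaries: IMSS (per-instant regional max of
|τ|), PMSS (per-vertex max over time), VASS (per-vertex time-mean of the
signed vertical traction component; vertical = the posture's anti-gravity
axis; the averaging window includes the post-saccade interval), ARSS
(per-instant area-weighted regional mean, barycentric vertex areas — never
vertex counts), IMSR (regional max of |τ|/(k·μ) with the engineering
convention k = 1 by default; k = 2 selects the strain-rate-tensor-magnitude
convention and is exposed as a flag, never silently applied). One caveat
worth knowing: over a mixed region the IMSR maximum is typically attained
at an aqueous-wetted vertex (small stress over tiny viscosity), so regional
IMSR at partial fills is aqueous-dominated and identical between oil
grades; restricted to oil-wetted wall (e.g. the 100% fill case) the
SiO1000:SiO5000 rate ratio is exactly √5.

## Synthetic fixtures

The separable traction fixture emulates the space–time structure the
Stokes-layer model actually produces — τ(x,t) = A(x)·b(t)·ê(x) with a
smooth positive amplitude field (seeded low-order spherical harmonics,
degree ≤ 3, so regional extrema are stable under meshing), a two-bump time
profile (the bimodality harness), and the tangential direction field of a
rigid rotation. Every generator returns its own closed-form metric values
alongside the data, and identical seed + spec gives bit-identical output.
What the fixtures do *not* emulate: non-separable traction (real CFD mixes
spatial and temporal structure through interface motion), so metric tests
on fixtures validate the metric algebra, not the flow physics.

## Problem sizes and determinism

Defaults used throughout the analysis scripts and acceptance checks: mesh
resolution 0.45 mm (10 242 vertices), 1 ms time step (275 samples), the
full 2×5×3 study grid (30 dynamic configurations over 15 unique static
equilibria). A capillary solve takes a few seconds at this resolution;
the full static sweep a couple of minutes. Every stage is deterministic —
the only randomness in the package is the seeded fixture generator — so
repeated runs produce identical tables.
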