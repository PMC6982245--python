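# Methods

This note documents the model behind `tonosim`, the choices that were
genuinely open, the calibration of the surrogate's closure constants, and
what the package does and does not claim about real eyes.

## Eye geometry

The anterior cornea is a conic section, sag
`z(r) = r² / (R + sqrt(R² − (1+Q) r²))`, with apical radius `R` (mm) and
asphericity `Q` (default −0.25, a typical prolate human cornea).  A CSV
elevation map (`r_mm, z_mm[, thickness_um]`) can replace the conic for
patient-specific anterior shapes; it is interpolated with a clamped cubic
spline (zero apical slope) and reproduces the grid to machine precision.
Corneal thickness grows quadratically from CCT at the apex to
`peripheral_thickness_ratio × CCT` (default 1.18) at the limbus; scleral
thickness follows average anatomical values (0.8 mm limbal, 0.45 mm
equatorial, 1.0 mm posterior) with an exponential blend at the junction.

The sclera is an idealised 11.5 mm spherical segment whose centre lies on
the optical axis and which passes through the corneal rim.  Exact tangent
continuity between two axis-centred spheres of different radii is
geometrically impossible; the junction is position-continuous and the small
slope break is absorbed by the limbus material band.  A normalized
meridional angle coordinate places the cornea on [0°, 40°] (measured about
its own apical centre of curvature) and maps the scleral arc linearly onto
[40°, 180°]; the five material regions are then the bands 0–40 (cornea),
40–50 (limbus), 50–90, 90–135 and 135–180 (anterior, equatorial, posterior
sclera).

The 3-D mesh revolves the meridian into rings × sectors × layers of
wedge/hexahedral cells — `(15 + 35) rings × 100 sectors × 2 layers =
10,000` elements at the defaults.  The azimuthal count (100) is a package
choice fixed by that element count; the mesh is used for geometry, volume,
export (legacy ASCII VTK with region tags) and the air-domain projection.
The air domain is built by similar triangles: anterior-surface nodes over
the cornea plus a 4 mm scleral ring are projected to the nozzle plane at
the 11 mm standoff, the nozzle-plane footprint shrunk by a single scale
factor (default: footprint → the 1.2 mm orifice radius); layer 0 keeps the
surface node numbering identically, the co-simulation precondition.

## Tissue and cavity mechanics

Tissue is incompressible first-order Ogden; the study's stiffness
coefficient μ is the corneal μ₁ with α = 110 fixed (α is not identifiable
from the study inputs; 110 gives the documented steep S-shaped stiffening
of stroma in the test's strain range).  Regional scaling: limbus 0.8×,
anterior/equatorial/posterior sclera 3.0/3.5/4.0× the corneal μ — fixed
multipliers standing in for age-adjusted scleral stiffening.  Tissue
density 1062 kg/m³.

The intraocular contents are a lumped fluid cavity:
`P = P_ref + K (V_ref − V)/V_ref`, K = 2.2·10³ MPa (water), density
1000 kg/m³.  `V_ref` is the cavity volume of the inflated measured geometry
at the measured IOP.  With K this large the fluid is effectively
incompressible and the IOP rise during the puff (~2–3 mmHg) is set by
scleral compliance, as in the real eye.

## Structural solver

All structural solves run on an axisymmetric meridian shell (the full 3-D
mesh is retained for geometry only): a nonlinear membrane from the
plane-stress incompressible Ogden reduction (λ₃ = 1/(λ_s λ_θ)) plus a
discrete-Kirchhoff bending surrogate — meridional hinge stiffness and a
hoop-curvature penalty with plate modulus `B = s_b · μ₀ t³/3`.  The bending
scale `s_b = 0.5` is a frozen calibration constant (below).  A
prestress-tangent bending law (`E_b = 3μ₀ + α σ_pre`) is implemented as an
option but off by default: it over-stiffens the stiff corner of the
parameter box and suppresses applanation there.

* **Static inflation** — damped Newton with load ramping on the
  pressure-controlled equilibrium `∂E/∂x = P ∂V/∂x`; forward-difference
  tangents on the free degrees of freedom (the force routines are fully
  vectorised and batched, so a Jacobian costs two force sweeps).
* **Stress-free inversion** — fixed-point iteration
  `X ← X − (inflate(X, IOP) − X_measured)` with tolerance 10⁻³ mm (max
  nodal error), max 50 iterations, divergence detected after three
  consecutive residual growths.  Converges in ≤ 10 iterations across the
  study ranges.
* **Dynamics** — implicit Newmark (β = 1/4, γ = 1/2) with exact boundary
  conditions (axis nodes fixed radially, equator fixed axially), lumped
  mass, and light stiffness-proportional Rayleigh damping
  (coefficient 10⁻⁵ ms, frozen equilibrium tangent) for robustness.
  Newton tolerances scale with the IOP load; line search plus Jacobian
  refresh on stagnation.

Verification oracles: Ogden α = 2 equals the neo-Hookean closed form to
10⁻¹²; internal forces match finite-difference energy gradients to 10⁻⁵;
thin-sphere inflation reproduces the Laplace law σ = PR/2t within 5 %; a
single-mass oscillator shows second-order convergence; an impulsively
loaded sphere conserves post-pulse energy to < 1 % with damping off.

## Jet surrogate and coupling

The turbulent jet is replaced by impinging-jet closures.  Temporal profile:
half-sine-squared ramp to `V_max = 167.8 m/s` at 16 ms, symmetric decay to
zero at 30 ms.  Centerline: full dynamic pressure `q = ½ ρ V²` while the
surface lies inside the potential core (`L_c = (D/2)/tan 5° = 13.7 mm >
11 mm standoff`), inverse-square decay beyond.  Spatial shape along the
surface arc length `s`:

    P(s) = q_eff exp(−(s/b)²) − c_s q_eff (s²/2b²) exp(1 − s²/2b²),
    b = c_w (D/2 + z_eff tan 8.5°)

— a stagnation bell plus a normalized suction lobe peaking at `s = b√2`
(the wall-jet annulus).  In coupled mode `z_eff = standoff + apex
displacement` and `q_eff` is divided by `1 + c_f κ_c`, where `κ_c` is the
central concavity of the deformed profile (apex indentation in excess of
the 2.5 mm rim, normalized by the orifice diameter).  Shear traction is
neglected.

The coupling loop is loose/staggered with one exchange per step, the jet
amplitude sampled at the step midpoint on the current geometry.  The
virtual air gap is regenerated from the surface each step and the step size
adapts so that no loaded node moves more than 0.45 of its local gap layer
(gap/12) per step — the boundary-motion analogue of a CFL cap.  Production
step cap is 0.1 ms (halving it changes the sampled apex trace by < 0.6 %
max-norm).  Traces are resampled at 0.231 ms, approximately the device
frame interval (140 frames / 31 ms).

**Energy audit.**  Work by the surface pressure (trapezoidal in space and
path) balances Δ(kinetic + strain + cavity) + Rayleigh dissipation.  The
loose-coupling work estimate converges first order in the step size; the
audit closes within 2 % on a refined-step run (0.05 ms cap) and within
~4 % at the production step.

## Calibration of the closure constants (frozen)

The three closure coefficients and the bending scale are the surrogate's
only fitted constants, each calibrated once and then frozen:

* `c_s = 0.15` — suction amplitude (the magnitude of the peripheral
  negative pressure is not independently constrained; only its location
  is used).
* `c_w = 0.555` — sets the rigid-mode suction minimum at 3.0 mm from the
  corneal centre for the default geometry (the documented annulus sits at
  2–4 mm).
* `c_f = 0.142` — sets the mean rigid→coupled peak apex-pressure decrease
  to 6.29 % over the default 10-model calibration sweep spanning the
  parameter ranges.
* `s_b = 0.5` — bending-penalty scale, chosen so the parametric sweep
  reproduces the documented correlation structure (IOP-dominant AP1 and
  A1-time correlations, positive μ correlations for A1 length and SP-HC)
  while all DCR outputs stay in their clinical ranges.

## DCR definitions

The applanated zone at time t is the central chord over which the anterior
profile deviates from a horizontal chord by ≤ 10 µm (search within ±4 mm,
0.02 mm spline resampling).  A1 is the first maximum of this chord length
during the inward phase (minimum 1 mm); this latches within ~1 frame of
the curvature-zero instant when flattening is crisp, and slightly later
for very gradual flattening.  A1 velocity is the apex speed in m/s
(≡ mm/ms).  AP1 is the on-cornea apex air pressure at A1 in mmHg — not a
fraction of a piston reading, since the surrogate provides the surface
pressure directly.  HC time/amplitude come from the parabolic-refined
maximum of apex displacement; peak distance is twice the radius of the
crest flanking the central concavity.  These operational definitions are
deliberately isolated in `dcr.py` so they can be revised without touching
the solver.

## Parametric study

Latin-hypercube sampling (seeded, scipy QMC) over the four input ranges;
grid mode for corner designs.  Failed rows are flagged and excluded
listwise; no multiple-testing correction is applied (raw two-tailed p
values).  Pearson r uses the textbook definition with
`t = r √((n−2)/(1−r²))` against Student-t (n−2).  Synthetic clinical
fixtures are truncated normals matching printed mean/SD/range rows — they
emulate marginal summary statistics only, not joint structure, device
noise, or repeated-measure variability, so agreement there says nothing
about real measurement error.

The acceptance script uses 10 paired models for the attenuation statistic
and a 40-model sweep for the correlation and timing statistics — problem
sizes chosen so the whole pipeline stays desk-scale while the statistics
(a mean over the box, a sign pattern, a strong correlation) are stable
across seeds.

## Known limitations

* **Amplitude bias.** The purely elastic shell (no viscoelastic
  hysteresis, a single loading path) overshoots deformation amplitudes:
  HC amplitude is ~1.3–2× the device-reported statistics (default model
  1.79 mm vs a clinical mean near 0.84 mm), and A1 length runs ~20 % long.
  Timing (A1, HC), pressures (AP1), the attenuation statistic and all
  correlation signs are unaffected; amplitude-dependent magnitudes should
  not be read as device-calibrated.
* The jet Reynolds number computed from the stated air properties
  (ρVD/μ = 2.65·10⁴ at peak) is reported from first principles; quoted
  figures near 2.3·10⁴ are not recoverable from those same properties.
* Axisymmetry: only centred, perpendicular puffs; no off-axis angle
  correction, eyelid/face geometry, or whole-globe retraction.
* The fluid side is a closure, not a discretised flow: no velocity fields,
  no turbulence quantities, and the suction magnitude is calibrated only
  by location.
* Bending uses a constant small-strain-based modulus; through-thickness
  stress gradients and the 15-node solid kinematics of full 3-D models are
  outside the surrogate.
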