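# Methods

## The model

A sand swimmer is represented as a planar chain of N = 60 rigid segments
(total length L = 12 cm, height 1.6 cm, total mass 14 g) connected by
rotary actuators.  Two body plans are provided: *uniform* (square
1.6 × 1.6 cm cross-section, flat ends) and *tapered* (coronal width ramping
linearly 0.2 → 1.6 cm over body positions 0 → 0.4 and back to 0.2 cm over
0.6 → 1, positions measured from the tail tip).  Per-segment mass is
proportional to width cubed and normalized to the total.

### Prescribed wave

The actuators realize a single-period sinusoidal wave of constant amplitude
travelling head to tail.  Because the chain is inextensible, the wave is
generated in arc-length form: the midline tangent angle at arc-length
fraction u = s/L is

    φ(u, t) = arctan(κ cos(2π(u + f t) + φ₀))

which carries exactly one period of curvature along the body.  The slope
parameter κ is calibrated by a scalar root solve so that the assembled
chain, fitted with a sinusoid, realizes the requested amplitude-to-
wavelength ratio A/λ; the realized wavelength λ is the chain's x-extent
over its period.  The calibration lands within 0.1% of the target (the
contract is 2%).  At A/λ = 0.2 (the default; the animal's preferred ratio):
κ ≈ 1.343, λ ≈ 9.12 cm, A ≈ 1.82 cm.  The phase origin φ₀ = π/2 places a
crest at the head at t = 0; all steady-state observables are phase-
independent.

### Granular force relations

Steady drag on a surface element in the frictional-fluid regime depends on
orientation only.  With ψ the attack angle between element velocity and the
element's in-surface direction, the force per reference element is

    F_⊥(ψ) = C_S sin β₀,   tan β₀ = γ tan ψ
    F_∥(ψ) = C_F cos ψ + C_L (1 − sin ψ)

with (C_S, C_F, C_L, γ) fitted per surface class — rod side (body) and rod
end cap (head) — for 3 mm glass particles, shipped in
`src/sandswim/data/rft_coefficients.csv`:

| surface | C_S (N) | C_F (N) | C_L (N) | γ |
|---------|---------|---------|---------|------|
| body    | 5.57    | 2.30    | −1.74   | 1.93 |
| head    | 19.52   | 1.24    | −0.99   | 0.14 |

Forces scale linearly with element area and centroid depth relative to the
reference geometry (rod side 1.6 × 4.0 cm at 7.6 cm depth).  ψ outside
[0, π/2] folds back by symmetry; each force component opposes its velocity
component, so F·v ≤ 0 always.  Below a speed floor of 10⁻⁹ λf the force is
zero (the law carries no rate dependence and is undefined at rest).

Two modelling choices deserve emphasis:

- **Cap orientation.**  The end cap's surface tangent is perpendicular to
  the segment axis, so its attack angle is measured from the cap *plane*:
  face-first motion is a 90° attack (the large C_S-governed normal force),
  edge-on motion a 0° attack.  Treating the cap like a side surface would
  make it strongest when sliding edgewise, which is unphysical.
- **Cap normalization.**  Both coefficient rows are normalized per the
  rod-side reference area (6.4 cm²), reading the fitted constants as the
  decomposition of the whole reference rod's force.  Normalizing the cap
  row by its own 2.56 cm² face would imply face-first cap stresses
  (~75 kPa at reference depth, ~70× the overburden) that exceed anything
  the rest of the body can balance: the quasi-static equilibrium then fails
  over much of the cycle and every reported kinematic quantity degrades.
  With the side-area normalization the head carries mean drags of order
  1–2 N at the default depth, consistent with the reported head-drag
  traces.

The tapered body has no cap: each segment carries two oblique coronal side
faces (half the sagittal area each, inclined by the local half-width slope,
body-class law), so nose faces acquire an axial drag component and the
summed nose load defines the tapered head drag.  The uniform body's flat
tail end is treated as sheltered (a trailing face sheds contact) and
carries no cap load.

### Quasi-static rigid-body dynamics

The three rigid degrees of freedom (v_x, v_y, ω) satisfy zero net force and
zero net torque about the instantaneous CoM at every sample (the
frictional force law makes body and grain inertia negligible; an
independent explicit integrator with the true 14 g mass distribution
reproduces the quasi-static wave efficiency and yaw to within a few
percent and serves as a cross-check).  The solve is a warm-started
3-variable root find (Powell hybrid) with least-squares polishing across
the force law's derivative kinks, nondimensionalized by the wave speed;
accepted roots satisfy |residual| < 10⁻⁸ × the typical single-segment
force.

At the head-cap load reversal there exist narrow phase pockets with *no*
exact equilibrium: the bounded, direction-only force law cannot close the
balance, and a massive body would briefly accelerate.  There the solver
returns the minimum-residual pseudo-equilibrium after a deterministic
multi-start sweep and records the residual per step
(`Trajectory.solver_residual`); at the default conditions >95% of steps are
exact roots, and the energetic consequence is bounded by the 1%
generation–dissipation balance check, which holds with large margin.

The pose advances by midpoint (RK2) integration at 200 samples per cycle
(default; observables change <0.5% between 100 and 200).  Runs cover three
steady cycles after a quarter-cycle discard — steady state is reached
within a quarter cycle because nothing in the system carries inertia.
Actuator torque at joint j is the negated moment of all head-side element
loads about the joint; computing it from the tail side gives the same value
(asserted), and cycle-averaged actuator power equals total medium
dissipation identically at exact equilibria.

Because forces are speed-independent, rescaling the frequency rescales all
velocities exactly: wave efficiency, CoT and every force-distribution shape
are frequency-invariant to solver precision, and power is exactly linear in
frequency.  These are asserted at 10⁻⁶ relative tolerance.

### Observables

- wave efficiency η = (cycle-mean forward CoM speed)/(fλ), with the forward
  axis defined as the mean swimming direction;
- per-segment RMS lateral displacement and its correlation decomposition
  against CoM lateral motion and yaw-induced motion (yaw measured from the
  tail-to-head chord, as for the study's yaw angle);
- head-drag power fraction, dimensionless mechanical cost of transport
  P/(m g v̄ₓ), and the origin-constrained power-vs-frequency slope;
- the closed-form inertial-force estimate F = c ρ V A ω² with c = 1,
  ρ = grain density × packing fraction ≈ 1.48 g/cm³, V the cube of the
  1.6 cm body height, A the realized amplitude, ω = 2πf.  It yields 0.07 N
  at 4 Hz and 0.28 N at 8 Hz, quadrupling per frequency doubling.

## Reduced-scale DEM

Soft spheres with the normal law F_n = k δ^(3/2) + G_n v_n δ^(1/2)
(clamped non-negative) and pure Coulomb sliding friction μ|F_n| (no
tangential spring), parameters in `src/sandswim/data/dem_contact.csv`:
k = 2×10⁶ N m^(−3/2), G_n = 15 N s m^(−3/2), μ_pp = 0.1, μ_bp = 0.27,
grain density 2470 kg/m³, diameters 3.0/3.4 mm at 50:50.  Two-body
integration at fine dt gives restitution 0.80–0.87 over impact speeds
0.1–1 m/s, against the tabulated 0.88 (validated at ±20%).

Integration is semi-implicit (symplectic) Euler with one force evaluation
per step; neighbor search uses uniform cells of one maximum diameter,
rebuilt every step; the inner loops are numba-compiled.  The time step
resolves the binary contact time ~25×.  Beds are periodic horizontally
with a flat frictional floor and an open top — a reduced desk-scale box
(default ~8 × 4 × 5 cm, 10⁴ grains; tests use ~6.5 × 3 × 4 cm, ~2.5×10³)
cannot offer a rod several widths of travel between side walls, so the
periodic geometry replaces the study's walled container.  Intruders are
rigid boxes with yaw; sphere–box contact uses closest-point projection
with the same normal law and μ_bp.

For desk runtimes the stiffness may be softened (default experiments use
0.25×, with the time step reduced accordingly); the quasi-static drag
force is insensitive to stiffness while the overlap guard holds (softening
to 0.1× was rejected because rod loading then produced ~10% grain
overlaps).

**Bed preparation** places grains on a jittered loose lattice (packing
~0.34) and settles them under gravity until the kinetic energy per grain
falls below 10⁻⁸ J.  The friction coefficient *during settling only* is a
protocol constant, 0.2, calibrated once so the settled bulk lands at
φ = 0.60 ± 0.01 (measured exactly by sphere–slab volume intersection over
the bulk, excluding one diameter at floor and surface); every prepared bed
re-validates this contract and preparation is bit-reproducible per seed.

**Experiments.**  Steady rod drag (square section, reduced 0.8 × 0.8 ×
2.4 cm rod) at prescribed attack angle, speed and depth, with discard and
steady averaging windows; speed independence and depth monotonicity are
the validated regime contracts.  The quasi-static window is narrower at
reduced scale: at 0.6 m/s the grain-inertial contribution ρAv² is no
longer negligible against the small frictional forces, so speed
independence is validated between 0.12 and 0.25 m/s.  Oscillating-rod
runs prescribe lateral sinusoidal displacement; each half-cycle
after the first, between successive velocity reversals, yields a
*transient fraction*: the part of the half-cycle before the low-pass
filtered |F| first reaches 90% of the half-cycle's plateau.  The plateau
is estimated over the last 20% of the stroke's *resistive phase*: near
each stroke's end the rod re-enters material it evacuated on the previous
pass and the signed force flips early, so the raw trailing window would
straddle a sign change (with no early flip the definition reduces to the
plain trailing 20%).  The fraction grows over the first strokes while the
disturbed zone develops, and at small amplitude the two stroke directions
weaken differently, so runs analyze an even (direction-balanced) number of
half-cycles — four by default — after the first.  Granular
temperature is the per-cell mean squared deviation of grain velocities
from the cell mean (0.3 × 0.3 × 1.6 cm cells), averaged over snapshots;
empty cells are missing, not zero.  A reduced swimmer (≤6 cm) can be
coupled directly to the bed through an explicit rigid-body update with the
scaled mass; a cost guard refuses runs whose step × particle count exceeds
a configurable ceiling.

## What the synthetic medium does and does not capture

The DEM bed reproduces the frictional-fluid regime (speed-independent,
depth-linear drag, drag anisotropy, transient weakening after reversals,
localized fluidization).  It is reduced in scale: absolute drag values at
the study's reference geometry and depth are not reproduced, only
rescaled properties and directions; fluctuations are larger than in a
full-size bed, so drag comparisons use fluctuation bands rather than
percentages.  Passing tests therefore demonstrate the regime contracts,
not grain-level realism of any specific sand.

## Known limitations

- The steady-state force relations overestimate forces near every velocity
  reversal (the transient-weakening effect the oscillating-rod experiments
  expose).  In the full 3-DoF dynamics this overdamps the head's lateral
  sway: the yaw pivot shifts toward the head, the yaw excursion roughly
  doubles relative to the inertial grain-resolved reference, the head's
  share of dissipation drops to ~16% (vs ~30%), and the "w"-shaped
  lateral-RMS profile loses its front arm.  These are properties of
  steady RFT, documented rather than patched; the DEM module exists
  precisely to expose them.
- No vertical (pitch/burial) dynamics; the swimming plane is fixed, with
  depth entering only through the force scaling (linearly along the body
  for a nonzero entry angle).
- No grain rotation in the DEM (pure sliding friction, as the contact law
  prescribes); no media other than the 3 mm glass parameter set.
- The quasi-static solver's fold pockets (above) are intrinsic to a
  bounded direction-only force law; their energetic effect is monitored,
  not eliminated.
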