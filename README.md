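# sandswim

Mechanics of undulatory swimming inside granular media — "sand swimming"
as performed by the sandfish lizard (*Scincus scincus*) — modelled with
granular resistive force theory (RFT) and a reduced-scale soft-sphere
discrete element method (DEM).

Dry granular media in the slow, frictional regime behave as a *frictional
fluid*: the resistive force on a moving intruder is independent of speed,
grows linearly with depth, and depends on the intruder's orientation
relative to its velocity.  A slender undulating body exploits the
anisotropy of those forces — broadside resistance exceeds axial
resistance — to generate net thrust, exactly as in viscous-fluid RFT but
with a different force law.

## What the package computes

**Swimmer model.** A planar chain of N = 60 rigid segments (12 cm, 14 g,
uniform or naturally tapered width) driven by joint actuators that realize
a single-period sinusoidal travelling wave of constant amplitude, moving
head to tail:

    y(ξ, t) = A sin(2π/λ (ξ + v_w t)),    v_w = f λ,   A/λ = 0.2 by default

Segment reaction forces come from empirical fitting functions of the attack
angle ψ (between segment velocity and axis), obtained from rod-drag
experiments in 3 mm glass particles:

    F_⊥ = C_S sin β₀,  tan β₀ = γ tan ψ;    F_∥ = C_F cos ψ + C_L (1 − sin ψ)

scaled linearly by surface area and depth; the blunt head carries the
rod-end-cap force law.  The three rigid degrees of freedom (forward,
lateral, yaw) are solved **quasi-statically**: net force and net torque
vanish at every instant, which is exact in the limit of negligible body and
grain inertia.  Actuator torques, per-joint power, per-segment dissipation,
wave efficiency η = v̄ₓ/(fλ), cost of transport P/(mgv̄ₓ), and the classic
single-DoF RFT speed balance are all exposed as library functions.

**Granular medium.** A soft-sphere DEM of the 50:50 bi-disperse 3.0/3.4 mm
glass-bead medium (Hertzian normal force with velocity-dependent
dissipation, Coulomb sliding friction) at packing fraction 0.60, reduced to
desk-scale beds with periodic horizontal boundaries.  It regenerates the
empirical force relations (rod drag vs attack angle, depth and speed),
exposes their limits through oscillating-rod transient/hysteresis
experiments, computes granular-temperature fields, and optionally couples a
reduced swimmer directly to the grains.

## Worked example

```
$ python examples/01_swim_uniform.py
wavelength               9.12 cm
wave efficiency eta      0.394
forward speed            7.19 cm/s
speed p2p / mean         0.42
max yaw excursion        15.9 deg
total mechanical power   936.7 mW
head-drag power fraction 0.16
cost of transport        94.8
```

The body advances at ~0.39 wavelengths per undulation cycle; the forward
speed oscillates at twice the undulation frequency because head drag surges
twice per cycle; power scales exactly linearly with frequency, so the cost
of transport is frequency-independent.  `examples/02_speed_balance.py`
sweeps the undulation amplitude and finds the efficiency optimum near the
amplitude the animal prefers; `examples/04_dem_drag.py` and
`examples/05_dem_hysteresis.py` run the granular-medium experiments.

A thin CLI wraps the same functionality:

```
sandswim simulate-rft --plan tapered --frequency 2
sandswim speed-balance --amplitude-ratio 0.2
sandswim dem-drag --psi-deg 90 --depth 0.015
sandswim report
```

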