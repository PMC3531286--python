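"""Derived quantities reported for sand-swimming runs.

All trajectory observables are computed over an integer number of steady
undulation cycles in the frame whose x-axis is the mean swimming direction
(the paper-standard measurement frame).  Because the granular force law is
speed-independent, wave efficiency, the cost of transport and every
force-distribution shape are exactly invariant under frequency rescaling,
and cycle-averaged power is exactly linear in frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .dynamics import GRAVITY, SwimConfig, Trajectory, power_accounting, simulate
from .kinematics import BODY_HEIGHT

__all__ = [
    "wave_efficiency",
    "LateralProfile",
    "lateral_profile",
    "EnergeticsSummary",
    "energetics",
    "power_frequency_sweep",
    "oscillation_metrics",
    "InertialEstimateParams",
    "inertial_force_estimate",
]

#: bulk density of the medium: glass grain density x packing fraction
MEDIUM_BULK_DENSITY = 2470.0 * 0.60  # kg/m^3


def _forward_frame(traj: Trajectory):
    """Unit vectors of the measurement frame (forward, lateral)."""
    fwd = traj.forward_axis()
    lat = np.array([-fwd[1], fwd[0]])
    return fwd, lat


def wave_efficiency(traj: Trajectory) -> float:
    """Cycle-averaged forward CoM speed / wave speed (f * lambda)."""
    if traj.wave.kappa == 0.0:
        return 0.0
    s = traj.steady()
    v = traj.com_velocity()[s]
    fwd, _ = _forward_frame(traj)
    return float((v @ fwd).mean() / traj.wave.wave_speed)


# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LateralProfile:
    """Per-segment lateral-displacement statistics over steady cycles."""

    positions: np.ndarray  # (N,) fraction of body length, 0 = tail
    rms: np.ndarray  # (N,) RMS lateral displacement (m)
    rms_normalized: np.ndarray  # (N,) rms / body length
    c_com: np.ndarray  # (N,) correlation with CoM lateral motion (m^2)
    c_yaw: np.ndarray  # (N,) correlation with yaw-induced motion (m^2)

    def minima_positions(self):
        """Body positions of the two interior local minima of the RMS."""
        r = self.rms
        idx = [i for i in range(1, len(r) - 1) if r[i] <= r[i - 1] and r[i] <= r[i + 1]]
        idx.sort(key=lambda i: r[i])
        pos = sorted(self.positions[i] for i in idx[:2])
        return np.array(pos)


def lateral_profile(traj: Trajectory, n_cycles: int | None = None) -> LateralProfile:
    """RMS lateral displacement per segment and its decomposition.

    The mean-subtracted lab-frame lateral position of each segment is
    correlated with the CoM lateral displacement and with the yaw-induced
    displacement (yaw angle x forward offset from the CoM) to attribute the
    "w"-shaped profile to whole-body motions.
    """
    s = traj.steady(n_cycles)
    fwd, lat = _forward_frame(traj)
    pos = traj.seg_pos[s]  # (nt, N, 2)
    y = pos @ lat
    x = pos @ fwd
    m = traj.body.masses
    com = (pos * m[None, :, None]).sum(axis=1) / m.sum()
    y_com = com @ lat
    x_com = com @ fwd
    dy = y - y.mean(axis=0)
    dy_com = y_com - y_com.mean()
    mean_dir = np.arctan2(fwd[1], fwd[0])
    theta = traj.yaw[s] - mean_dir
    dtheta = theta - theta.mean()
    x_rel = x - x_com[:, None]
    dy_yaw = dtheta[:, None] * x_rel
    rms = np.sqrt((dy**2).mean(axis=0))
    return LateralProfile(
        positions=traj.body.positions,
        rms=rms,
        rms_normalized=rms / traj.body.length,
        c_com=(dy * dy_com[:, None]).mean(axis=0),
        c_yaw=(dy * dy_yaw).mean(axis=0),
    )


# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EnergeticsSummary:
    total_power: float  # cycle-averaged mechanical power (W)
    head_fraction: float  # head dissipation / total dissipation
    cost_of_transport: float  # P / (m g v), dimensionless (per Tucker)
    forward_speed: float  # m/s
    power_per_cycle: float  # total_power / f (J)


def energetics(traj: Trajectory, mass: float | None = None) -> EnergeticsSummary:
    """Cycle-averaged power, head-drag fraction and dimensionless CoT."""
    if mass is None:
        mass = float(traj.body.masses.sum())
    ps = power_accounting(traj)
    s = traj.steady()
    fwd, _ = _forward_frame(traj)
    v = float((traj.com_velocity()[s] @ fwd).mean())
    if v <= 0:
        raise ValueError("no net forward transport; CoT undefined")
    return EnergeticsSummary(
        total_power=ps.dissipation_total,
        head_fraction=ps.head_power / ps.dissipation_total,
        cost_of_transport=ps.dissipation_total / (mass * GRAVITY * v),
        forward_speed=v,
        power_per_cycle=ps.dissipation_total / traj.frequency,
    )


@dataclass(frozen=True)
class PowerFrequencySweep:
    frequencies: np.ndarray
    powers: np.ndarray  # cycle-averaged total power (W)
    slope: float  # origin-constrained fit of P vs f (J)
    r_squared: float


def power_frequency_sweep(config: SwimConfig, frequencies) -> PowerFrequencySweep:
    """Cycle-averaged power across an undulation-frequency sweep.

    Fits ``P = slope * f`` constrained through the origin (slope in Joules,
    the energy per cycle) and reports the fit's R^2.
    """
    frequencies = np.asarray(frequencies, dtype=float)
    powers = []
    for f in frequencies:
        cfg = replace(config, wave=replace(config.wave, frequency=float(f)))
        traj = simulate(cfg)
        powers.append(power_accounting(traj).dissipation_total)
    powers = np.asarray(powers)
    slope = float((powers * frequencies).sum() / (frequencies**2).sum())
    resid = powers - slope * frequencies
    ss_tot = ((powers - powers.mean()) ** 2).sum()
    r2 = 1.0 - float((resid**2).sum() / ss_tot) if ss_tot > 0 else 1.0
    return PowerFrequencySweep(frequencies=frequencies, powers=powers, slope=slope, r_squared=r2)


# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OscillationMetrics:
    speed_peak_to_peak_ratio: float  # (max - min)/mean of forward speed, one cycle
    max_yaw_deg: float  # max |yaw| about the mean direction, degrees
    speed_oscillation_frequency_ratio: float  # dominant v_x frequency / f


def oscillation_metrics(traj: Trajectory) -> OscillationMetrics:
    """Forward-speed oscillation and yaw excursion over one steady cycle."""
    if traj.wave.kappa == 0.0 or not np.any(traj.vel):
        return OscillationMetrics(0.0, 0.0, 0.0)
    spc = traj.samples_per_cycle
    one = slice(traj.steady_start, traj.steady_start + spc)
    fwd, _ = _forward_frame(traj)
    vx = traj.com_velocity()[one] @ fwd
    mean = vx.mean()
    ratio = float((vx.max() - vx.min()) / mean) if mean != 0 else 0.0
    mean_dir = np.arctan2(fwd[1], fwd[0])
    yaw = np.degrees(np.abs(traj.yaw[one] - mean_dir)).max() if traj.wave.kappa else 0.0
    # dominant oscillation frequency of v_x in units of the undulation frequency
    dv = vx - mean
    if np.allclose(dv, 0):
        fratio = 0.0
    else:
        spec = np.abs(np.fft.rfft(dv))
        fratio = float(np.argmax(spec[1:]) + 1)
    return OscillationMetrics(
        speed_peak_to_peak_ratio=ratio,
        max_yaw_deg=float(yaw),
        speed_oscillation_frequency_ratio=fratio,
    )


# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class InertialEstimateParams:
    """Parameters of the analytic inertial-force estimate.

    The undulating body accelerates a characteristic cube of granular
    material; the resulting reaction on a body patch scales as
    ``F = c * rho * V * A * omega^2`` with omega = 2 pi f.  Defaults: unit
    geometric coefficient, accelerated cube with the body-height side
    (1.6 cm), medium bulk density of 3 mm glass at packing fraction 0.60,
    and the realized undulation amplitude of the default wave.
    """

    amplitude: float  # undulation amplitude A (m)
    geometric_coefficient: float = 1.0
    cube_side: float = BODY_HEIGHT  # m; accelerated volume V = side^3
    density: float = MEDIUM_BULK_DENSITY  # kg/m^3, voids included
    patch_area: float = 0.5 * BODY_HEIGHT**2  # m^2 (half the head face; reporting only)

    @property
    def volume(self) -> float:
        return self.cube_side**3

    def validate(self):
        for name in ("amplitude", "geometric_coefficient", "cube_side", "density"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


def inertial_force_estimate(params: InertialEstimateParams, frequency: float) -> float:
    """Analytic inertial contribution to the force on a body patch (N)."""
    params.validate()
    omega = 2 * np.pi * frequency
    return params.geometric_coefficient * params.density * params.volume * params.amplitude * omega**2
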