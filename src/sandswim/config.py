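"""Run configuration: schema, validation, hashing and experiment bundles.

Configs are plain YAML mappings mirroring :class:`RunConfig`.  Units are SI
internally; lengths in config files may carry explicit ``_cm`` suffixed keys
where noted.  Every output table is comma-separated with a header row and
``#``-prefixed manifest lines recording the config hash, seeds, solver
tolerances and wall-clock.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dynamics import DEFAULT_DEPTH, SwimConfig, Trajectory, actuator_torque, power_accounting, simulate
from .kinematics import ConfigurationError, WaveSpec
from .observables import (
    energetics,
    lateral_profile,
    oscillation_metrics,
    power_frequency_sweep,
    wave_efficiency,
)

__all__ = ["RunConfig", "load_config", "config_hash", "run_experiment", "write_report", "make_fixtures"]


@dataclass(frozen=True)
class RunConfig:
    """Serializable description of one experiment."""

    experiment: str = "simulate-rft"
    plan: str = "uniform"
    amplitude_ratio: float = 0.2
    frequency: float = 2.0
    depth: float = DEFAULT_DEPTH
    entry_angle_deg: float = 0.0
    n_cycles: float = 3.0
    samples_per_cycle: int = 200
    seed: int = 0
    outdir: str = "runs"
    coefficients_path: str | None = None
    dem: dict = field(default_factory=dict)

    def swim_config(self) -> SwimConfig:
        return SwimConfig(
            plan=self.plan,
            wave=WaveSpec(amplitude_ratio=self.amplitude_ratio, frequency=self.frequency),
            depth=self.depth,
            entry_angle_deg=self.entry_angle_deg,
            n_cycles=self.n_cycles,
            samples_per_cycle=self.samples_per_cycle,
            coefficients_path=self.coefficients_path,
        )


_FIELD_TYPES = {
    "experiment": str,
    "plan": str,
    "amplitude_ratio": (int, float),
    "frequency": (int, float),
    "depth": (int, float),
    "entry_angle_deg": (int, float),
    "n_cycles": (int, float),
    "samples_per_cycle": int,
    "seed": int,
    "outdir": str,
    "coefficients_path": (str, type(None)),
    "dem": dict,
}


def load_config(path_or_mapping) -> RunConfig:
    """Load and validate a config; errors name the offending field path."""
    if isinstance(path_or_mapping, (str, Path)):
        with open(path_or_mapping) as fh:
            data = yaml.safe_load(fh) or {}
    else:
        data = dict(path_or_mapping)
    if not isinstance(data, dict):
        raise ConfigurationError("config root must be a mapping")
    unknown = set(data) - set(_FIELD_TYPES)
    if unknown:
        raise ConfigurationError(f"unknown config fields: {sorted(unknown)}")
    for key, typ in _FIELD_TYPES.items():
        if key in data and not isinstance(data[key], typ):
            raise ConfigurationError(f"field '{key}': expected {typ}, got {type(data[key]).__name__}")
    cfg = RunConfig(**data)
    cfg.swim_config().validate()
    return cfg


def config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(asdict(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _manifest_lines(cfg: RunConfig, extra=None):
    lines = [
        f"# config_hash: {config_hash(cfg)}",
        f"# seed: {cfg.seed}",
        f"# experiment: {cfg.experiment}",
        f"# solver_force_tolerance: 1e-8 (relative to typical segment force)",
        f"# generated_unix: {int(time.time())}",
    ]
    if extra:
        lines += [f"# {k}: {v}" for k, v in extra.items()]
    return lines


def _write_table(df: pd.DataFrame, path: Path, cfg: RunConfig, extra=None):
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("\n".join(_manifest_lines(cfg, extra)) + "\n")
        df.to_csv(fh, index=False)


def trajectory_tables(traj: Trajectory):
    """Body, per-segment and per-joint tables of a trajectory (SI units)."""
    v = traj.com_velocity()
    body = pd.DataFrame({
        "t_s": traj.t,
        "x_m": traj.pose[:, 0],
        "y_m": traj.pose[:, 1],
        "theta_rad": traj.pose[:, 2],
        "yaw_rad": traj.yaw,
        "vx_m_s": v[:, 0],
        "vy_m_s": v[:, 1],
        "omega_rad_s": traj.vel[:, 2],
        "head_fx_N": traj.head_force[:, 0],
        "head_fy_N": traj.head_force[:, 1],
        "total_dissipation_W": traj.total_dissipation,
        "solver_residual": traj.solver_residual,
    })
    nt, n = traj.seg_pos.shape[:2]
    tt = np.repeat(traj.t, n)
    seg = pd.DataFrame({
        "t_s": tt,
        "segment": np.tile(np.arange(n), nt),
        "x_m": traj.seg_pos[:, :, 0].ravel(),
        "y_m": traj.seg_pos[:, :, 1].ravel(),
        "fx_N": traj.seg_force[:, :, 0].ravel(),
        "fy_N": traj.seg_force[:, :, 1].ravel(),
        "power_W": traj.seg_power.ravel(),
    })
    tj = np.repeat(traj.t, n - 1)
    joints = pd.DataFrame({
        "t_s": tj,
        "joint": np.tile(np.arange(n - 1), nt),
        "torque_N_m": traj.joint_torque.ravel(),
        "rate_rad_s": traj.joint_rate.ravel(),
        "power_W": traj.joint_power.ravel(),
    })
    return body, seg, joints


def run_experiment(cfg: RunConfig, outdir: str | Path | None = None) -> dict:
    """Run the configured experiment and write its deterministic bundle."""
    out = Path(outdir if outdir is not None else cfg.outdir) / f"{cfg.experiment}-{config_hash(cfg)}"
    traj = simulate(cfg.swim_config())
    body, seg, joints = trajectory_tables(traj)
    _write_table(body, out / "body.csv", cfg, {"wavelength_m": traj.wavelength})
    _write_table(seg, out / "segments.csv", cfg)
    _write_table(joints, out / "joints.csv", cfg)
    return {"outdir": out, "trajectory": traj}


def write_report(cfg: RunConfig, outdir: str | Path | None = None,
                 sweep_frequencies=(1.0, 2.0, 3.0, 4.0)) -> Path:
    """Emit the standard result tables for a config.

    Covers: body-velocity/yaw time series, lateral-displacement profile and
    its CoM/yaw correlation decomposition, torque RMS profile, actuator and
    segment power profiles, and the power-vs-frequency sweep with its
    origin-constrained slope.
    """
    out = Path(outdir if outdir is not None else cfg.outdir) / f"report-{config_hash(cfg)}"
    traj = simulate(cfg.swim_config())
    body, _, _ = trajectory_tables(traj)
    _write_table(body, out / "kinematics.csv", cfg)
    lp = lateral_profile(traj)
    _write_table(pd.DataFrame({
        "position": lp.positions,
        "rms_m": lp.rms,
        "rms_over_L": lp.rms_normalized,
        "c_com_m2": lp.c_com,
        "c_yaw_m2": lp.c_yaw,
    }), out / "lateral_profile.csv", cfg)
    _, rms = actuator_torque(traj)
    ps = power_accounting(traj)
    _write_table(pd.DataFrame({
        "joint_position": (np.arange(len(rms)) + 1) / traj.body.n_segments,
        "torque_rms_N_m": rms,
        "actuator_power_W": ps.joint_profile,
    }), out / "torque_power_profile.csv", cfg)
    _write_table(pd.DataFrame({
        "position": traj.body.positions,
        "segment_dissipation_W": ps.segment_profile,
    }), out / "segment_dissipation.csv", cfg)
    sweep = power_frequency_sweep(traj.config, sweep_frequencies)
    _write_table(pd.DataFrame({
        "frequency_Hz": sweep.frequencies,
        "power_W": sweep.powers,
    }), out / "power_frequency.csv", cfg,
        {"slope_J": sweep.slope, "r_squared": sweep.r_squared})
    en = energetics(traj)
    om = oscillation_metrics(traj)
    _write_table(pd.DataFrame([{
        "wave_efficiency": wave_efficiency(traj),
        "head_fraction": en.head_fraction,
        "cost_of_transport": en.cost_of_transport,
        "total_power_W": en.total_power,
        "speed_p2p_over_mean": om.speed_peak_to_peak_ratio,
        "max_yaw_deg": om.max_yaw_deg,
        "speed_osc_freq_ratio": om.speed_oscillation_frequency_ratio,
    }]), out / "summary.csv", cfg)
    return out


def make_fixtures(seed: int = 0, outdir: str | Path = "fixtures") -> dict:
    """Generate miniature test fixtures: a settled bed and a 1-cycle run.

    The bed holds <= 2000 grains; the trajectory is one steady cycle of the
    default uniform swimmer at reduced sampling.  Regeneration with the same
    seed reproduces the files checksum-identically.
    """
    from .dem import prepare_bed

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = RunConfig(experiment="fixtures", n_cycles=1.0, samples_per_cycle=100, seed=seed)
    traj = simulate(cfg.swim_config())
    body, _, _ = trajectory_tables(traj)
    _write_table(body, out / "trajectory_1cycle.csv", cfg)
    bed = prepare_bed(dims=(0.045, 0.028, 0.026), seed=seed, stiffness_scale=0.25)
    dfb = pd.DataFrame({
        "id": np.arange(bed.n),
        "x_m": bed.x[:, 0], "y_m": bed.x[:, 1], "z_m": bed.x[:, 2],
        "r_m": bed.r,
        "vx_m_s": bed.v[:, 0], "vy_m_s": bed.v[:, 1], "vz_m_s": bed.v[:, 2],
    })
    _write_table(dfb, out / "mini_bed.csv", cfg, {
        "bed_seed": bed.seed, "phi": f"{bed.phi:.4f}",
        "box_xy_m": bed.box_xy, "surface_z_m": f"{bed.surface_z:.5f}",
    })
    checksums = {}
    for p in sorted(out.glob("*.csv")):
        h = hashlib.sha256()
        # hash content minus the volatile timestamp line
        for line in p.read_text().splitlines():
            if not line.startswith("# generated_unix"):
                h.update(line.encode())
        checksums[p.name] = h.hexdigest()[:16]
    (out / "checksums.json").write_text(json.dumps(checksums, indent=1))
    return {"outdir": out, "bed": bed, "trajectory": traj, "checksums": checksums}
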