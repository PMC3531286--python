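"""Preparation of settled bi-disperse granular beds.

The paper-standard medium is a 50:50 (by number) mixture of 3.0 and 3.4 mm
glass spheres at an initial packing fraction of 0.60.  The preparation
protocol here is the package's own: grains are placed on a jittered loose
lattice and settle under gravity until the kinetic energy per grain falls
below 1e-8 J; the protocol's friction during settling is a fixed constant
calibrated once so the settled packing lands at phi = 0.60 +/- 0.01 and is
then validated by measurement on every prepared bed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .contact import ContactModel, load_contact_model
from .engine import kinetic_energy, step_chunk, suggest_dt

__all__ = ["Bed", "prepare_bed", "packing_fraction"]

#: friction coefficient used only while settling the pour (protocol constant,
#: calibrated once so the settled bulk lands at phi = 0.60 +/- 0.01; the
#: contact model's own mu_pp applies in every experiment afterwards)
SETTLE_MU = 0.2

GRAVITY_Z = -9.81


@dataclass
class Bed:
    """A settled particle packing with box geometry."""

    x: np.ndarray  # (n, 3) positions, m
    v: np.ndarray  # (n, 3) velocities, m/s
    r: np.ndarray  # (n,) radii, m
    m: np.ndarray  # (n,) masses, kg
    box_xy: tuple  # (Lx, Ly) periodic horizontal extent
    seed: int
    model: ContactModel
    phi: float  # measured packing fraction of the bulk
    surface_z: float  # estimated free-surface height
    gravity: float = GRAVITY_Z

    @property
    def n(self) -> int:
        return len(self.r)

    def copy(self) -> "Bed":
        return Bed(self.x.copy(), self.v.copy(), self.r.copy(), self.m.copy(),
                   self.box_xy, self.seed, self.model, self.phi, self.surface_z,
                   self.gravity)

    def depth_of(self, z: float) -> float:
        """Depth below the free surface of a height ``z``."""
        return self.surface_z - z


def _sphere_slab_volume(zc, r, zlo, zhi):
    """Exact volume of spheres (centers zc, radii r) inside the slab [zlo, zhi]."""
    # V(h) = volume of sphere below plane at height h above the sphere bottom
    def below(h):
        h = np.clip(h, 0.0, 2 * r)
        return np.pi * h**2 * (3 * r - h) / 3.0

    return (below(zhi - (zc - r)) - below(zlo - (zc - r))).sum()


def packing_fraction(bed_or_x, r=None, box_xy=None, zlo=None, zhi=None) -> float:
    """Solids fraction within a horizontal slab (defaults to the bulk)."""
    if isinstance(bed_or_x, Bed):
        x, r, box_xy = bed_or_x.x, bed_or_x.r, bed_or_x.box_xy
    else:
        x = bed_or_x
    z = x[:, 2]
    dmax = 2 * r.max()
    if zlo is None:
        zlo = z.min() + dmax
    if zhi is None:
        zhi = np.quantile(z, 0.98) - dmax
    if zhi <= zlo:
        raise ValueError("bed too shallow to measure a bulk packing fraction")
    vol = _sphere_slab_volume(z, r, zlo, zhi)
    return float(vol / (box_xy[0] * box_xy[1] * (zhi - zlo)))


def prepare_bed(
    dims=(0.08, 0.04, 0.05),
    phi_target: float = 0.60,
    seed: int = 0,
    model: ContactModel | None = None,
    stiffness_scale: float = 1.0,
    phi_tol: float = 0.01,
    settle: bool = True,
) -> Bed:
    """Pour and settle a bed of nominal size ``dims = (Lx, Ly, depth)``.

    The grain count is chosen so the settled column is ``depth`` deep at the
    target packing fraction.  Deterministic per seed.  Raises if the settled
    bulk fraction misses ``phi_target`` by more than ``phi_tol``, reporting
    the achieved value.
    """
    model = model or load_contact_model()
    if stiffness_scale != 1.0:
        model = model.softened(stiffness_scale)
    Lx, Ly, depth = dims
    d_big = model.diameter_large
    if min(Lx, Ly, depth) < 5 * d_big:
        raise ValueError("each box dimension must hold at least 5 grain diameters")
    rng = np.random.default_rng(seed)
    r_small = model.diameter_small / 2
    r_large = model.diameter_large / 2
    vbar = 0.5 * (4 / 3 * np.pi * r_small**3) + 0.5 * (4 / 3 * np.pi * r_large**3)
    n = int(round(phi_target * Lx * Ly * depth / vbar))
    radii = np.where(rng.random(n) < model.large_fraction, r_large, r_small)
    masses = model.density * 4 / 3 * np.pi * radii**3

    # loose jittered lattice pour
    phi_init = 0.34
    a = (vbar / phi_init) ** (1 / 3)
    nx = max(1, int(Lx / a))
    ny = max(1, int(Ly / a))
    ax, ay = Lx / nx, Ly / ny
    pos = np.zeros((n, 3))
    idx = 0
    layer = 0
    while idx < n:
        for iy in range(ny):
            for ix in range(nx):
                if idx >= n:
                    break
                pos[idx] = [(ix + 0.5) * ax, (iy + 0.5) * ay, (layer + 0.8) * a]
                idx += 1
        layer += 1
    pos[:, :2] += rng.uniform(-0.2, 0.2, size=(n, 2)) * a
    pos[:, 0] %= Lx
    pos[:, 1] %= Ly
    pos[:, 2] += rng.uniform(-0.05, 0.05, size=n) * a
    vel = np.zeros((n, 3))

    if not settle:
        # loose pour, pre-compaction: phi measured over the occupied column
        phi = packing_fraction(pos, radii, (Lx, Ly),
                               zlo=pos[:, 2].min(), zhi=np.quantile(pos[:, 2], 0.95))
        surface_z = float(np.quantile(pos[:, 2] + radii, 0.98))
        return Bed(x=pos, v=vel, r=radii, m=masses, box_xy=(Lx, Ly), seed=seed,
                   model=model, phi=phi, surface_z=surface_z)

    v_char = max(1.0, np.sqrt(2 * 9.81 * layer * a))
    dt = suggest_dt(model, v_char)
    nobox = np.zeros((0, 3))
    nobox_s = np.zeros(0)
    chunk = 1500
    t_sim, t_max = 0.0, 3.0
    while t_sim < t_max:
        step_chunk(pos, vel, radii, masses, Lx, Ly, model.k, model.g_n,
                   SETTLE_MU, model.mu_bp, GRAVITY_Z, dt, chunk,
                   nobox.copy(), nobox_s.copy(), nobox.copy(), nobox.copy(), nobox_s.copy())
        t_sim += chunk * dt
        ke = kinetic_energy(vel, masses) / n
        if ke < 1e-8 and t_sim > 0.15:
            break
    vel[:] = 0.0

    phi = packing_fraction(pos, radii, (Lx, Ly))
    if abs(phi - phi_target) > phi_tol:
        raise RuntimeError(
            f"settled packing fraction {phi:.4f} outside {phi_target} +/- {phi_tol}"
        )
    surface_z = float(np.quantile(pos[:, 2] + radii, 0.98))
    return Bed(x=pos, v=vel, r=radii, m=masses, box_xy=(Lx, Ly), seed=seed,
               model=model, phi=phi, surface_z=surface_z)
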