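"""Soft-sphere contact law for the granular medium.

Contacting objects overlap virtually by ``delta``; the normal force is a
Hertzian hardness term plus a velocity-dependent viscoelastic term,

    F_n = k * delta^(3/2) + G_n * v_n * delta^(1/2)      (clamped >= 0)

with ``v_n`` the normal approach speed (positive while approaching), and
the tangential force is pure Coulomb sliding friction, mu * |F_n|, opposing
the relative tangential surface velocity.  Parameter values for the 3.0/3.4
mm bi-disperse glass medium ship in ``data/dem_contact.csv``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources

import numpy as np
import pandas as pd

__all__ = ["ContactModel", "load_contact_model", "pair_force", "normal_force_magnitude"]


@dataclass(frozen=True)
class ContactModel:
    """Grain material and contact-law constants."""

    k: float  # hardness, N m^-3/2
    g_n: float  # normal viscoelastic constant, N s m^-3/2
    mu_pp: float  # particle-particle friction
    mu_bp: float  # body-particle friction
    restitution: float  # two-body normal restitution (validation value)
    density: float  # grain density, kg/m^3
    diameter_small: float = 3.0e-3
    diameter_large: float = 3.4e-3
    large_fraction: float = 0.5

    def __post_init__(self):
        if self.k < 0 or self.g_n < 0:
            raise ValueError("k and g_n must be >= 0")
        if not (0 <= self.mu_pp <= 2 and 0 <= self.mu_bp <= 2):
            raise ValueError("friction coefficients must lie in [0, 2]")
        if self.diameter_small <= 0 or self.diameter_large <= 0:
            raise ValueError("diameters must be positive")

    def softened(self, scale: float) -> "ContactModel":
        """Return a copy with stiffness scaled down (desk-runtime option).

        Quasi-static drag forces are insensitive to stiffness as long as the
        overlap guard (< 1% of radius) holds; the time step must be reduced
        from the resulting contact time.
        """
        return replace(self, k=self.k * scale, g_n=self.g_n * np.sqrt(scale))


def load_contact_model(path=None) -> ContactModel:
    """Load the packaged contact parameters, or a user file (same schema)."""
    if path is None:
        with resources.files("sandswim.data").joinpath("dem_contact.csv").open() as fh:
            df = pd.read_csv(fh)
    else:
        df = pd.read_csv(path)
    p = dict(zip(df.parameter, df.value.astype(float)))
    return ContactModel(
        k=p["hardness_k"],
        g_n=p["viscoelastic_g_n"],
        mu_pp=p["mu_particle_particle"],
        mu_bp=p["mu_body_particle"],
        restitution=p["restitution"],
        density=p["grain_density"],
        diameter_small=p["diameter_small"],
        diameter_large=p["diameter_large"],
        large_fraction=p["large_fraction"],
    )


def normal_force_magnitude(delta, v_n, model: ContactModel):
    """Normal force magnitude; ``v_n > 0`` while approaching."""
    delta = np.asarray(delta, dtype=float)
    f = model.k * delta**1.5 + model.g_n * np.asarray(v_n) * np.sqrt(delta)
    return np.maximum(f, 0.0)


def pair_force(pos1, pos2, vel1, vel2, r1, r2, model: ContactModel, mu: float | None = None):
    """Contact forces on two spheres; returns ``(f1, f2)`` with f2 = -f1.

    The overlap is ``delta = r1 + r2 - |pos2 - pos1|`` (no force if
    negative).  The normal force pushes the spheres apart and includes the
    viscoelastic term; the tangential Coulomb force opposes the relative
    tangential velocity.  ``mu`` defaults to the particle-particle value.
    """
    if mu is None:
        mu = model.mu_pp
    pos1 = np.asarray(pos1, float)
    pos2 = np.asarray(pos2, float)
    d = pos2 - pos1
    dist = float(np.linalg.norm(d))
    delta = r1 + r2 - dist
    if delta <= 0.0 or dist == 0.0:
        return np.zeros(3), np.zeros(3)
    n = d / dist  # unit normal from 1 toward 2
    v_rel = np.asarray(vel1, float) - np.asarray(vel2, float)
    v_n = float(v_rel @ n)  # > 0 while approaching
    fn = float(normal_force_magnitude(delta, v_n, model))
    v_t = v_rel - v_n * n
    vt_mag = float(np.linalg.norm(v_t))
    ft = -mu * fn * v_t / vt_mag if (fn > 0 and vt_mag > 1e-12) else np.zeros(3)
    f1 = -fn * n + ft
    return f1, -f1
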