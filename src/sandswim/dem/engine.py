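"""Soft-sphere DEM integrator with cell-list neighbor search (numba).

Geometry: a box periodic in x and y, a flat frictional floor at z = 0 and
an open top; gravity acts in -z.  Intruders are rigid boxes (rod segments)
with a yaw angle about z, kinematically driven or externally integrated;
sphere-box contacts use closest-point projection with the same normal law
and the body-particle friction coefficient.

Integration is semi-implicit (symplectic) Euler: one force evaluation per
step, velocities updated before positions.  The inner loops are JIT
compiled; the Python layer orchestrates chunks of steps between intruder
updates and snapshot records.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["step_chunk", "kinetic_energy", "suggest_dt", "max_overlap_fraction"]


@njit(cache=True, fastmath=True)
def _build_cells(x, Lx, Ly, zmax, cell):
    n = x.shape[0]
    ncx = max(1, int(Lx / cell))
    ncy = max(1, int(Ly / cell))
    ncz = max(1, int(zmax / cell) + 1)
    cx, cy, cz = Lx / ncx, Ly / ncy, zmax / ncz if zmax > 0 else cell
    head = -np.ones(ncx * ncy * ncz, dtype=np.int64)
    nxt = -np.ones(n, dtype=np.int64)
    for i in range(n):
        ix = int(x[i, 0] / cx) % ncx
        iy = int(x[i, 1] / cy) % ncy
        iz = min(max(int(x[i, 2] / cz), 0), ncz - 1)
        c = ix + ncx * (iy + ncy * iz)
        nxt[i] = head[c]
        head[c] = i
    return head, nxt, ncx, ncy, ncz


@njit(cache=True, fastmath=True)
def _forces(x, v, r, f, Lx, Ly, k, gn, mu_pp, mu_bp,
            box_c, box_yaw, box_h, box_v, box_om, nbox,
            box_f, box_tq):
    n = x.shape[0]
    for i in range(n):
        f[i, 0] = 0.0
        f[i, 1] = 0.0
        f[i, 2] = 0.0
    for b in range(nbox):
        box_f[b, 0] = 0.0
        box_f[b, 1] = 0.0
        box_f[b, 2] = 0.0
        box_tq[b] = 0.0
    rmax = 0.0
    zmax = 0.0
    for i in range(n):
        if r[i] > rmax:
            rmax = r[i]
        if x[i, 2] > zmax:
            zmax = x[i, 2]
    cell = 2.0 * rmax * 1.001
    head, nxt, ncx, ncy, ncz = _build_cells(x, Lx, Ly, zmax + cell, cell)
    cx, cy = Lx / ncx, Ly / ncy
    cz = (zmax + cell) / ncz
    maxov = 0.0
    # particle-particle
    for i in range(n):
        ix = int(x[i, 0] / cx) % ncx
        iy = int(x[i, 1] / cy) % ncy
        iz = min(max(int(x[i, 2] / cz), 0), ncz - 1)
        for dz in range(-1, 2):
            jz = iz + dz
            if jz < 0 or jz >= ncz:
                continue
            for dy in range(-1, 2):
                jy = (iy + dy) % ncy
                for dx in range(-1, 2):
                    jx = (ix + dx) % ncx
                    j = head[jx + ncx * (jy + ncy * jz)]
                    while j >= 0:
                        if j > i:
                            ddx = x[j, 0] - x[i, 0]
                            ddy = x[j, 1] - x[i, 1]
                            ddz = x[j, 2] - x[i, 2]
                            if ddx > 0.5 * Lx:
                                ddx -= Lx
                            elif ddx < -0.5 * Lx:
                                ddx += Lx
                            if ddy > 0.5 * Ly:
                                ddy -= Ly
                            elif ddy < -0.5 * Ly:
                                ddy += Ly
                            rsum = r[i] + r[j]
                            d2 = ddx * ddx + ddy * ddy + ddz * ddz
                            if d2 < rsum * rsum and d2 > 0.0:
                                dist = np.sqrt(d2)
                                delta = rsum - dist
                                ov = delta / min(r[i], r[j])
                                if ov > maxov:
                                    maxov = ov
                                nx_, ny_, nz_ = ddx / dist, ddy / dist, ddz / dist
                                rvx = v[i, 0] - v[j, 0]
                                rvy = v[i, 1] - v[j, 1]
                                rvz = v[i, 2] - v[j, 2]
                                vn = rvx * nx_ + rvy * ny_ + rvz * nz_
                                fn = k * delta * np.sqrt(delta) + gn * vn * np.sqrt(delta)
                                if fn < 0.0:
                                    fn = 0.0
                                vtx = rvx - vn * nx_
                                vty = rvy - vn * ny_
                                vtz = rvz - vn * nz_
                                vt = np.sqrt(vtx * vtx + vty * vty + vtz * vtz)
                                ftx = fty = ftz = 0.0
                                if vt > 1e-12 and fn > 0.0:
                                    s = -mu_pp * fn / vt
                                    ftx, fty, ftz = s * vtx, s * vty, s * vtz
                                # normal force pushes i away from j (i is at -n side)
                                f[i, 0] += -fn * nx_ + ftx
                                f[i, 1] += -fn * ny_ + fty
                                f[i, 2] += -fn * nz_ + ftz
                                f[j, 0] -= -fn * nx_ + ftx
                                f[j, 1] -= -fn * ny_ + fty
                                f[j, 2] -= -fn * nz_ + ftz
                        j = nxt[j]
    # floor at z = 0
    for i in range(n):
        delta = r[i] - x[i, 2]
        if delta > 0.0:
            vn = -v[i, 2]  # approaching when moving down
            fn = k * delta * np.sqrt(delta) + gn * vn * np.sqrt(delta)
            if fn < 0.0:
                fn = 0.0
            vt = np.sqrt(v[i, 0] * v[i, 0] + v[i, 1] * v[i, 1])
            ftx = fty = 0.0
            if vt > 1e-12 and fn > 0.0:
                s = -mu_pp * fn / vt
                ftx, fty = s * v[i, 0], s * v[i, 1]
            f[i, 2] += fn
            f[i, 0] += ftx
            f[i, 1] += fty
    # box intruders
    for b in range(nbox):
        cyw = np.cos(box_yaw[b])
        syw = np.sin(box_yaw[b])
        hx, hy, hz = box_h[b, 0], box_h[b, 1], box_h[b, 2]
        for i in range(n):
            px = x[i, 0] - box_c[b, 0]
            py = x[i, 1] - box_c[b, 1]
            pz = x[i, 2] - box_c[b, 2]
            if px > 0.5 * Lx:
                px -= Lx
            elif px < -0.5 * Lx:
                px += Lx
            if py > 0.5 * Ly:
                py -= Ly
            elif py < -0.5 * Ly:
                py += Ly
            # early reject
            reach = r[i] + np.sqrt(hx * hx + hy * hy + hz * hz)
            if px * px + py * py + pz * pz > reach * reach:
                continue
            # rotate into box frame
            qx = cyw * px + syw * py
            qy = -syw * px + cyw * py
            qz = pz
            ax = min(max(qx, -hx), hx)
            ay = min(max(qy, -hy), hy)
            az = min(max(qz, -hz), hz)
            dx_ = qx - ax
            dy_ = qy - ay
            dz_ = qz - az
            d2 = dx_ * dx_ + dy_ * dy_ + dz_ * dz_
            if d2 > r[i] * r[i]:
                continue
            if d2 > 1e-24:
                dist = np.sqrt(d2)
                delta = r[i] - dist
                nxb, nyb, nzb = dx_ / dist, dy_ / dist, dz_ / dist
            else:
                # center inside the box: push out along the least-penetrated face
                m0 = hx - abs(qx)
                m1 = hy - abs(qy)
                m2 = hz - abs(qz)
                if m0 <= m1 and m0 <= m2:
                    nxb = 1.0 if qx >= 0 else -1.0
                    nyb = nzb = 0.0
                    delta = r[i] + m0
                elif m1 <= m2:
                    nyb = 1.0 if qy >= 0 else -1.0
                    nxb = nzb = 0.0
                    delta = r[i] + m1
                else:
                    nzb = 1.0 if qz >= 0 else -1.0
                    nxb = nyb = 0.0
                    delta = r[i] + m2
                ax, ay, az = qx, qy, qz
            # contact normal in world frame (points from box surface to grain)
            nwx = cyw * nxb - syw * nyb
            nwy = syw * nxb + cyw * nyb
            nwz = nzb
            # contact point in world frame (relative to box center)
            cwx = cyw * ax - syw * ay
            cwy = syw * ax + cyw * ay
            cwz = az
            # box surface velocity at contact
            bvx = box_v[b, 0] - box_om[b] * cwy
            bvy = box_v[b, 1] + box_om[b] * cwx
            bvz = box_v[b, 2]
            rvx = v[i, 0] - bvx
            rvy = v[i, 1] - bvy
            rvz = v[i, 2] - bvz
            vn = -(rvx * nwx + rvy * nwy + rvz * nwz)  # approaching > 0
            fn = k * delta * np.sqrt(delta) + gn * vn * np.sqrt(delta)
            if fn < 0.0:
                fn = 0.0
            vnc = rvx * nwx + rvy * nwy + rvz * nwz
            vtx = rvx - vnc * nwx
            vty = rvy - vnc * nwy
            vtz = rvz - vnc * nwz
            vt = np.sqrt(vtx * vtx + vty * vty + vtz * vtz)
            ftx = fty = ftz = 0.0
            if vt > 1e-12 and fn > 0.0:
                s = -mu_bp * fn / vt
                ftx, fty, ftz = s * vtx, s * vty, s * vtz
            fgx = fn * nwx + ftx
            fgy = fn * nwy + fty
            fgz = fn * nwz + ftz
            f[i, 0] += fgx
            f[i, 1] += fgy
            f[i, 2] += fgz
            box_f[b, 0] -= fgx
            box_f[b, 1] -= fgy
            box_f[b, 2] -= fgz
            box_tq[b] -= cwx * fgy - cwy * fgx
    return maxov


@njit(cache=True, fastmath=True)
def step_chunk(x, v, r, m, Lx, Ly, k, gn, mu_pp, mu_bp, gz, dt, nsteps,
               box_c, box_yaw, box_h, box_v, box_om):
    """Advance ``nsteps`` steps in place; boxes translate/rotate at their
    (constant) velocities.  Returns (per-step box forces (nsteps, nb, 3),
    per-step box torques (nsteps, nb), max overlap fraction seen)."""
    n = x.shape[0]
    nbox = box_c.shape[0]
    f = np.zeros((n, 3))
    box_f = np.zeros((nbox, 3))
    box_tq = np.zeros(nbox)
    out_f = np.zeros((nsteps, nbox, 3))
    out_t = np.zeros((nsteps, nbox))
    maxov = 0.0
    for s in range(nsteps):
        ov = _forces(x, v, r, f, Lx, Ly, k, gn, mu_pp, mu_bp,
                     box_c, box_yaw, box_h, box_v, box_om, nbox, box_f, box_tq)
        if ov > maxov:
            maxov = ov
        for i in range(n):
            v[i, 0] += dt * f[i, 0] / m[i]
            v[i, 1] += dt * f[i, 1] / m[i]
            v[i, 2] += dt * (f[i, 2] / m[i] + gz)
            x[i, 0] = (x[i, 0] + dt * v[i, 0]) % Lx
            x[i, 1] = (x[i, 1] + dt * v[i, 1]) % Ly
            x[i, 2] += dt * v[i, 2]
        for b in range(nbox):
            box_c[b, 0] = (box_c[b, 0] + dt * box_v[b, 0]) % Lx
            box_c[b, 1] = (box_c[b, 1] + dt * box_v[b, 1]) % Ly
            box_c[b, 2] += dt * box_v[b, 2]
            box_yaw[b] += dt * box_om[b]
            out_f[s, b, 0] = box_f[b, 0]
            out_f[s, b, 1] = box_f[b, 1]
            out_f[s, b, 2] = box_f[b, 2]
            out_t[s, b] = box_tq[b]
    return out_f, out_t, maxov


def kinetic_energy(v, m):
    """Total translational kinetic energy (J)."""
    return 0.5 * float((m * (np.asarray(v) ** 2).sum(axis=1)).sum())


def max_overlap_fraction(x, r, Lx, Ly):
    """Largest pair overlap as a fraction of the smaller radius (brute force)."""
    n = len(r)
    worst = 0.0
    for i in range(n):
        d = x[i + 1:] - x[i]
        d[:, 0] -= Lx * np.round(d[:, 0] / Lx)
        d[:, 1] -= Ly * np.round(d[:, 1] / Ly)
        dist = np.linalg.norm(d, axis=1)
        rsum = r[i] + r[i + 1:]
        ov = (rsum - dist) / np.minimum(r[i], r[i + 1:])
        if len(ov) and ov.max() > worst:
            worst = float(ov.max())
    return worst


def suggest_dt(model, v_char: float = 1.0, resolution: int = 25) -> float:
    """Time step from the binary-collision contact time at ``v_char``.

    The maximum Hertz overlap at impact speed v is (5 m v^2 / 4 k)^(2/5);
    the contact duration is of order pi * delta_max / v.  The step resolves
    that duration ``resolution`` times.
    """
    r_min = model.diameter_small / 2
    m_min = model.density * 4 / 3 * np.pi * r_min**3
    m_eff = m_min / 2
    delta_max = (5 * m_eff * v_char**2 / (4 * model.k)) ** 0.4
    tau = np.pi * delta_max / v_char
    return float(tau / resolution)
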