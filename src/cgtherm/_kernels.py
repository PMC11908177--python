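"""Numba-compiled inner loops: pair forces and the Langevin integrator.

All kernels operate on plain arrays so they stay independent of the object
model.  Per-type-pair parameters arrive as (ntype, ntype) matrices built by
``md_engine.build_tables``.  Interaction kinds: 0 none, 1 attractive
Wang-Frenkel, 2 repulsive (WCA-style truncation at the WF minimum).
Electrostatics are Yukawa with an energy shift at the cutoff.

Bonded (consecutive beads of one molecule) pairs are excluded from the
nonbonded sums and interact through the harmonic bond only.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from cgtherm.constants import FTM2V


@njit(cache=True, inline="always")
def _pair_eval(r, kind, eps, sigma, mu, nu, rcut, alpha, rstar,
               coulpref, kappa, ycut, yshift):
    """Energy and radial force (-dU/dr) for one pair at separation r."""
    e = 0.0
    f = 0.0
    if kind == 1 and r < rcut:
        sig_t = (sigma / r) ** (2.0 * mu)
        cut_t = (rcut / r) ** (2.0 * mu)
        a = sig_t - 1.0
        b = cut_t - 1.0
        bpow = b ** (2.0 * nu)
        e += eps * alpha * a * bpow
        da = -2.0 * mu * sig_t / r
        db = -2.0 * mu * cut_t / r
        f += -eps * alpha * (da * bpow + a * 2.0 * nu * b ** (2.0 * nu - 1.0) * db)
    elif kind == 2 and r < rstar:
        sig_t = (sigma / r) ** (2.0 * mu)
        cut_t = (rcut / r) ** (2.0 * mu)
        a = sig_t - 1.0
        b = cut_t - 1.0
        bpow = b ** (2.0 * nu)
        e += -eps * alpha * a * bpow - eps
        da = -2.0 * mu * sig_t / r
        db = -2.0 * mu * cut_t / r
        f += eps * alpha * (da * bpow + a * 2.0 * nu * b ** (2.0 * nu - 1.0) * db)
    if coulpref != 0.0 and r < ycut:
        ucoul = coulpref * np.exp(-kappa * r) / r
        e += ucoul - yshift
        f += ucoul * (kappa + 1.0 / r)
    return e, f


@njit(cache=True)
def forces_allpairs(pos, box, types, mol, kind, eps, sigma, mu, nu, rcut,
                    alpha, rstar, coulpref, kappa, ycut, yshift, maxcut):
    """O(N^2) nonbonded forces with the minimum-image convention."""
    n = pos.shape[0]
    forces = np.zeros((n, 3))
    pe = 0.0
    cut2 = maxcut * maxcut
    for i in range(n):
        ti = types[i]
        for j in range(i + 1, n):
            if mol[i] == mol[j] and (j - i) == 1:
                continue  # bonded exclusion
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            dx -= box[0] * np.rint(dx / box[0])
            dy -= box[1] * np.rint(dy / box[1])
            dz -= box[2] * np.rint(dz / box[2])
            r2 = dx * dx + dy * dy + dz * dz
            if r2 >= cut2 or r2 == 0.0:
                continue
            r = np.sqrt(r2)
            tj = types[j]
            e, f = _pair_eval(
                r, kind[ti, tj], eps[ti, tj], sigma[ti, tj], mu[ti, tj],
                nu[ti, tj], rcut[ti, tj], alpha[ti, tj], rstar[ti, tj],
                coulpref[ti, tj], kappa, ycut, yshift[ti, tj],
            )
            pe += e
            fx = f * dx / r
            fy = f * dy / r
            fz = f * dz / r
            forces[i, 0] += fx
            forces[i, 1] += fy
            forces[i, 2] += fz
            forces[j, 0] -= fx
            forces[j, 1] -= fy
            forces[j, 2] -= fz
    return forces, pe


@njit(cache=True)
def forces_celllist(pos, box, types, mol, kind, eps, sigma, mu, nu, rcut,
                    alpha, rstar, coulpref, kappa, ycut, yshift, maxcut):
    """Linked-cell nonbonded forces; requires >= 3 cells per dimension."""
    n = pos.shape[0]
    forces = np.zeros((n, 3))
    pe = 0.0
    cut2 = maxcut * maxcut

    ncx = max(int(box[0] / maxcut), 1)
    ncy = max(int(box[1] / maxcut), 1)
    ncz = max(int(box[2] / maxcut), 1)
    ncells = ncx * ncy * ncz
    head = np.full(ncells, -1, dtype=np.int64)
    nxt = np.full(n, -1, dtype=np.int64)
    for i in range(n):
        cx = int(pos[i, 0] / box[0] * ncx) % ncx
        cy = int(pos[i, 1] / box[1] * ncy) % ncy
        cz = int(pos[i, 2] / box[2] * ncz) % ncz
        c = (cx * ncy + cy) * ncz + cz
        nxt[i] = head[c]
        head[c] = i

    for cx in range(ncx):
        for cy in range(ncy):
            for cz in range(ncz):
                c = (cx * ncy + cy) * ncz + cz
                i = head[c]
                while i >= 0:
                    ti = types[i]
                    for ox in range(-1, 2):
                        for oy in range(-1, 2):
                            for oz in range(-1, 2):
                                nx = (cx + ox) % ncx
                                ny = (cy + oy) % ncy
                                nz = (cz + oz) % ncz
                                c2 = (nx * ncy + ny) * ncz + nz
                                j = head[c2]
                                while j >= 0:
                                    if j > i:
                                        if not (mol[i] == mol[j] and (j - i) == 1):
                                            dx = pos[i, 0] - pos[j, 0]
                                            dy = pos[i, 1] - pos[j, 1]
                                            dz = pos[i, 2] - pos[j, 2]
                                            dx -= box[0] * np.rint(dx / box[0])
                                            dy -= box[1] * np.rint(dy / box[1])
                                            dz -= box[2] * np.rint(dz / box[2])
                                            r2 = dx * dx + dy * dy + dz * dz
                                            if 0.0 < r2 < cut2:
                                                r = np.sqrt(r2)
                                                tj = types[j]
                                                e, f = _pair_eval(
                                                    r, kind[ti, tj], eps[ti, tj],
                                                    sigma[ti, tj], mu[ti, tj],
                                                    nu[ti, tj], rcut[ti, tj],
                                                    alpha[ti, tj], rstar[ti, tj],
                                                    coulpref[ti, tj], kappa,
                                                    ycut, yshift[ti, tj],
                                                )
                                                pe += e
                                                fx = f * dx / r
                                                fy = f * dy / r
                                                fz = f * dz / r
                                                forces[i, 0] += fx
                                                forces[i, 1] += fy
                                                forces[i, 2] += fz
                                                forces[j, 0] -= fx
                                                forces[j, 1] -= fy
                                                forces[j, 2] -= fz
                                    j = nxt[j]
                    i = nxt[i]
    return forces, pe


@njit(cache=True)
def bond_forces(pos, box, bonds, r0, k):
    """Harmonic bonds U = k (r - r0)^2; returns (forces, energy)."""
    n = pos.shape[0]
    forces = np.zeros((n, 3))
    pe = 0.0
    for m in range(bonds.shape[0]):
        i = bonds[m, 0]
        j = bonds[m, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dx -= box[0] * np.rint(dx / box[0])
        dy -= box[1] * np.rint(dy / box[1])
        dz -= box[2] * np.rint(dz / box[2])
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r == 0.0:
            continue
        pe += k * (r - r0) ** 2
        fmag = -2.0 * k * (r - r0)
        fx = fmag * dx / r
        fy = fmag * dy / r
        fz = fmag * dz / r
        forces[i, 0] += fx
        forces[i, 1] += fy
        forces[i, 2] += fz
        forces[j, 0] -= fx
        forces[j, 1] -= fy
        forces[j, 2] -= fz
    return forces, pe


@njit(cache=True)
def total_forces(pos, box, types, mol, bonds, bond_r0, bond_k,
                 kind, eps, sigma, mu, nu, rcut, alpha, rstar,
                 coulpref, kappa, ycut, yshift, maxcut, use_cells):
    if use_cells:
        f, pe = forces_celllist(pos, box, types, mol, kind, eps, sigma, mu,
                                nu, rcut, alpha, rstar, coulpref, kappa,
                                ycut, yshift, maxcut)
    else:
        f, pe = forces_allpairs(pos, box, types, mol, kind, eps, sigma, mu,
                                nu, rcut, alpha, rstar, coulpref, kappa,
                                ycut, yshift, maxcut)
    fb, peb = bond_forces(pos, box, bonds, bond_r0, bond_k)
    return f + fb, pe + peb


@njit(cache=True)
def baoab_chunk(pos, vel, mass, noise, dt, gamma, sigv,
                box, types, mol, bonds, bond_r0, bond_k,
                kind, eps, sigma, mu, nu, rcut, alpha, rstar,
                coulpref, kappa, ycut, yshift, maxcut, use_cells):
    """BAOAB Langevin steps in place; returns (potential_energy, ok_flag).

    ``noise`` has shape (nsteps, N, 3); ``sigv`` is the per-particle thermal
    velocity sqrt(kB T / m) in A/fs; ``gamma`` in 1/fs.  With gamma == 0 the
    scheme reduces to velocity Verlet (noise ignored).
    """
    nsteps = noise.shape[0]
    n = pos.shape[0]
    half_min_box = 0.5 * min(box[0], min(box[1], box[2]))
    a_coef = np.exp(-gamma * dt)
    b_coef = np.sqrt(max(0.0, 1.0 - a_coef * a_coef))

    f, pe = total_forces(pos, box, types, mol, bonds, bond_r0, bond_k,
                         kind, eps, sigma, mu, nu, rcut, alpha, rstar,
                         coulpref, kappa, ycut, yshift, maxcut, use_cells)
    for s in range(nsteps):
        for i in range(n):
            inv = FTM2V / mass[i]
            for d in range(3):
                vel[i, d] += 0.5 * dt * f[i, d] * inv
        for i in range(n):
            for d in range(3):
                step_len = 0.5 * dt * vel[i, d]
                if abs(step_len) > half_min_box:
                    return pe, False
                pos[i, d] += step_len
        if gamma > 0.0:
            for i in range(n):
                for d in range(3):
                    vel[i, d] = a_coef * vel[i, d] + b_coef * sigv[i] * noise[s, i, d]
        for i in range(n):
            for d in range(3):
                step_len = 0.5 * dt * vel[i, d]
                if abs(step_len) > half_min_box:
                    return pe, False
                pos[i, d] += step_len
                pos[i, d] -= np.floor(pos[i, d] / box[d]) * box[d]
        f, pe = total_forces(pos, box, types, mol, bonds, bond_r0, bond_k,
                             kind, eps, sigma, mu, nu, rcut, alpha, rstar,
                             coulpref, kappa, ycut, yshift, maxcut, use_cells)
        for i in range(n):
            inv = FTM2V / mass[i]
            for d in range(3):
                vel[i, d] += 0.5 * dt * f[i, d] * inv
    return pe, True
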