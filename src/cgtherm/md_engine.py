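"""Desk-scale canonical-ensemble Langevin dynamics.

The integrator is a BAOAB splitting of Langevin dynamics (velocity Verlet
when the friction is zero) with friction 1/(5 ps) by default and a 10 fs
timestep, matching the slab-simulation protocol.  Forces come from numba
kernels; the cell-list path is used automatically when the box admits at
least three cells per dimension and is validated against the O(N^2)
reference in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from cgtherm import _kernels
from cgtherm.constants import KB, MVV2E, T_MAX, T_MIN
from cgtherm.forcefield.electrostatics import dielectric, inverse_debye_length
from cgtherm.forcefield.parameters import ForceFieldParameters
from cgtherm.forcefield.potentials import (
    effective_epsilon,
    wf_alpha,
    wf_r_star,
)
from cgtherm.constants import COULOMB
from cgtherm.system_builder import ParticleSystem


class InstabilityError(RuntimeError):
    """A bead moved more than half the box in a single step."""


@dataclass
class SimulationProtocol:
    """Run-length and thermostat settings (times in ns unless noted)."""

    timestep: float = 10.0  # fs
    thermostat_relaxation: float = 5.0  # ps
    equilibration: float = 0.0  # ns
    production: float = 0.0  # ns
    sample_interval: float = 1.0  # ns
    temperature_grid: tuple[float, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.timestep <= 0:
            raise ValueError("timestep must be positive")
        if self.production < 0 or self.equilibration < 0:
            raise ValueError("run lengths must be non-negative")
        for t in self.temperature_grid:
            if not (T_MIN <= t <= T_MAX):
                raise ValueError(f"grid temperature {t} outside [{T_MIN}, {T_MAX}] K")

    @property
    def friction(self) -> float:
        """1/fs; zero disables the thermostat."""
        if self.thermostat_relaxation <= 0:
            return 0.0
        return 1.0 / (self.thermostat_relaxation * 1000.0)


@dataclass
class Frame:
    time: float  # ns
    positions: np.ndarray
    box: np.ndarray


@dataclass
class Trajectory:
    frames: list[Frame] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)


@dataclass
class RuntimeTables:
    """Per-type interaction matrices for a (force field, codes, T) triple."""

    codes: str
    types: np.ndarray
    mol: np.ndarray
    mass: np.ndarray
    bonds: np.ndarray
    bond_r0: float
    bond_k: float
    kind: np.ndarray
    eps: np.ndarray
    sigma: np.ndarray
    mu: np.ndarray
    nu: np.ndarray
    rcut: np.ndarray
    alpha: np.ndarray
    rstar: np.ndarray
    coulpref: np.ndarray
    kappa: float
    ycut: float
    yshift: np.ndarray
    maxcut: float


def build_tables(system: ParticleSystem, T: float, ff: ForceFieldParameters) -> RuntimeTables:
    codes = sorted(set(system.residue_codes))
    type_of = {c: k for k, c in enumerate(codes)}
    nt = len(codes)
    seq = system.residue_codes
    types = np.array([type_of[c] for c in seq], dtype=np.int64)
    mol = system.molecule_ids()
    mass = system.masses(ff)

    kind = np.zeros((nt, nt), dtype=np.int64)
    eps = np.zeros((nt, nt))
    sigma = np.ones((nt, nt))
    mu = np.ones((nt, nt))
    nu = np.ones((nt, nt))
    rcut = np.ones((nt, nt))
    alpha = np.zeros((nt, nt))
    rstar = np.ones((nt, nt))
    coulpref = np.zeros((nt, nt))
    yshift = np.zeros((nt, nt))

    es = ff.electrostatics
    eps_r = dielectric(T, es.d_coefficients)
    kappa = inverse_debye_length(T, es)
    ycut = es.yukawa_cutoff

    maxcut = 0.0
    any_coul = False
    for a in codes:
        for b in codes:
            ia, ib = type_of[a], type_of[b]
            pair = ff.pair(a, b)
            e = effective_epsilon(T, a, b, ff)
            eps[ia, ib] = e
            sigma[ia, ib] = pair.sigma_ij
            mu[ia, ib] = pair.mu_ij
            nu[ia, ib] = pair.nu_ij
            rcut[ia, ib] = pair.r_cut
            alpha[ia, ib] = wf_alpha(pair)
            rstar[ia, ib] = wf_r_star(pair)
            if e > 0:
                kind[ia, ib] = 1
                maxcut = max(maxcut, pair.r_cut)
            elif e < 0:
                kind[ia, ib] = 2
                maxcut = max(maxcut, rstar[ia, ib])
            qa = ff.residue(a).charge
            qb = ff.residue(b).charge
            if qa != 0.0 and qb != 0.0:
                pref = COULOMB * qa * qb / eps_r
                coulpref[ia, ib] = pref
                yshift[ia, ib] = (
                    pref * math.exp(-kappa * ycut) / ycut if es.shift_at_cutoff else 0.0
                )
                any_coul = True
    if any_coul:
        maxcut = max(maxcut, ycut)
    if maxcut == 0.0:
        maxcut = 1.0  # no nonbonded interactions at all

    return RuntimeTables(
        codes="".join(codes), types=types, mol=mol, mass=mass,
        bonds=system.bonds().astype(np.int64),
        bond_r0=ff.bond.r0, bond_k=ff.bond.k,
        kind=kind, eps=eps, sigma=sigma, mu=mu, nu=nu, rcut=rcut,
        alpha=alpha, rstar=rstar, coulpref=coulpref,
        kappa=kappa, ycut=ycut, yshift=yshift, maxcut=maxcut,
    )


def _use_cells(tables: RuntimeTables, box: np.ndarray) -> bool:
    return bool(np.all(box / tables.maxcut >= 3.0))


def _kernel_args(tables: RuntimeTables, box: np.ndarray):
    return (
        box, tables.types, tables.mol, tables.bonds, tables.bond_r0,
        tables.bond_k, tables.kind, tables.eps, tables.sigma, tables.mu,
        tables.nu, tables.rcut, tables.alpha, tables.rstar, tables.coulpref,
        tables.kappa, tables.ycut, tables.yshift, tables.maxcut,
    )


def compute_forces(
    system: ParticleSystem,
    T: float,
    ff: ForceFieldParameters,
    tables: RuntimeTables | None = None,
    use_cells: bool | None = None,
) -> tuple[np.ndarray, float]:
    """Total forces (kcal/mol/A) and potential energy (kcal/mol)."""
    if tables is None:
        tables = build_tables(system, T, ff)
    if use_cells is None:
        use_cells = _use_cells(tables, system.box)
    return _kernels.total_forces(
        system.positions, *_kernel_args(tables, system.box), use_cells
    )


def potential_energy(system: ParticleSystem, T: float, ff: ForceFieldParameters) -> float:
    return compute_forces(system, T, ff)[1]


def kinetic_energy(system: ParticleSystem, ff: ForceFieldParameters) -> float:
    m = system.masses(ff)
    return 0.5 * float(np.sum(m[:, None] * system.velocities**2)) * MVV2E


def kinetic_temperature(system: ParticleSystem, ff: ForceFieldParameters) -> float:
    ke = kinetic_energy(system, ff)
    dof = 3 * system.n_beads
    return 2.0 * ke / (dof * KB)


def thermalize_velocities(
    system: ParticleSystem, T: float, ff: ForceFieldParameters, rng: np.random.Generator
) -> None:
    """Maxwell-Boltzmann velocities at T, with net momentum removed."""
    m = system.masses(ff)
    sig = np.sqrt(KB * T / (m * MVV2E))
    system.velocities = rng.normal(size=(system.n_beads, 3)) * sig[:, None]
    p = (m[:, None] * system.velocities).sum(axis=0)
    system.velocities -= p / m.sum()


def _run_chunk(
    system: ParticleSystem,
    tables: RuntimeTables,
    n_steps: int,
    dt: float,
    friction: float,
    T: float,
    rng: np.random.Generator,
) -> float:
    sigv = np.sqrt(KB * T / (tables.mass * MVV2E))
    if friction > 0:
        noise = rng.standard_normal((n_steps, system.n_beads, 3))
    else:
        noise = np.zeros((n_steps, system.n_beads, 3))
    use_cells = _use_cells(tables, system.box)
    pe, ok = _kernels.baoab_chunk(
        system.positions, system.velocities, tables.mass, noise, dt, friction,
        sigv, *_kernel_args(tables, system.box), use_cells,
    )
    if not ok:
        raise InstabilityError(
            "bead displacement exceeded half the box in one step; "
            "reduce the timestep or relax the starting configuration"
        )
    return pe


def step(
    system: ParticleSystem,
    T: float,
    ff: ForceFieldParameters,
    dt: float = 10.0,
    friction: float = 1.0 / 5000.0,
    rng: np.random.Generator | None = None,
    tables: RuntimeTables | None = None,
) -> ParticleSystem:
    """Advance one BAOAB Langevin step in place; returns the system."""
    if rng is None:
        rng = np.random.default_rng(0)
    if tables is None:
        tables = build_tables(system, T, ff)
    _run_chunk(system, tables, 1, dt, friction, T, rng)
    return system


def run(
    system: ParticleSystem,
    protocol: SimulationProtocol,
    ff: ForceFieldParameters,
    temperature: float | None = None,
    observers: list | None = None,
    thermalize: bool = True,
) -> Trajectory:
    """Equilibrate then sample; observers are called as obs(time_ns, system).

    Returns the production trajectory only (equilibration is discarded).
    """
    if temperature is None:
        if not protocol.temperature_grid:
            raise ValueError("no temperature given and protocol grid is empty")
        temperature = protocol.temperature_grid[0]
    observers = observers or []
    rng = np.random.default_rng(protocol.seed)
    tables = build_tables(system, temperature, ff)
    system.temperature = temperature
    if thermalize:
        thermalize_velocities(system, temperature, ff, rng)

    dt = protocol.timestep
    steps_per_ns = int(round(1e6 / dt))
    eq_steps = int(round(protocol.equilibration * steps_per_ns))
    sample_steps = max(int(round(protocol.sample_interval * steps_per_ns)), 1)
    prod_steps = int(round(protocol.production * steps_per_ns))
    friction = protocol.friction

    chunk = 2000
    remaining = eq_steps
    while remaining > 0:
        n = min(chunk, remaining)
        _run_chunk(system, tables, n, dt, friction, temperature, rng)
        remaining -= n

    traj = Trajectory()
    n_samples = prod_steps // sample_steps
    for s in range(n_samples):
        done = 0
        while done < sample_steps:
            n = min(chunk, sample_steps - done)
            _run_chunk(system, tables, n, dt, friction, temperature, rng)
            done += n
        t_ns = (s + 1) * sample_steps * dt / 1e6
        traj.frames.append(
            Frame(time=t_ns, positions=system.positions.copy(), box=system.box.copy())
        )
        for obs in observers:
            obs(t_ns, system)
    return traj


def minimize(
    system: ParticleSystem,
    T: float,
    ff: ForceFieldParameters,
    n_steps: int = 100,
    max_displacement: float = 0.1,
) -> list[float]:
    """Steepest descent with step-size backtracking; returns energy history."""
    tables = build_tables(system, T, ff)
    use_cells = _use_cells(tables, system.box)
    args = _kernel_args(tables, system.box)
    f, pe = _kernels.total_forces(system.positions, *args, use_cells)
    history = [pe]
    step_size = max_displacement
    for _ in range(n_steps):
        fmax = np.abs(f).max()
        if fmax == 0:
            break
        trial = system.positions + f * (step_size / fmax)
        trial -= np.floor(trial / system.box) * system.box
        f_new, pe_new = _kernels.total_forces(trial, *args, use_cells)
        if pe_new <= pe:
            system.positions = trial
            f, pe = f_new, pe_new
            step_size = min(step_size * 1.2, max_displacement)
        else:
            step_size *= 0.5
            if step_size < 1e-12:
                break
        history.append(pe)
    return history


# -------------------------------------------------------------- trajectory I/O

def write_dump(path: str | Path, traj: Trajectory, system: ParticleSystem) -> None:
    """LAMMPS-style text dump (id type x y z), one block per frame."""
    codes = sorted(set(system.residue_codes))
    type_of = {c: k + 1 for k, c in enumerate(codes)}
    seq = system.residue_codes
    with open(path, "w") as fh:
        for frame in traj:
            fh.write("ITEM: TIMESTEP\n")
            fh.write(f"{int(round(frame.time * 1e6))}\n")  # fs as integer steps
            fh.write("ITEM: NUMBER OF ATOMS\n")
            fh.write(f"{frame.positions.shape[0]}\n")
            fh.write("ITEM: BOX BOUNDS pp pp pp\n")
            for d in range(3):
                fh.write(f"0.0 {frame.box[d]:.8f}\n")
            fh.write("ITEM: ATOMS id type x y z\n")
            for i, p in enumerate(frame.positions):
                fh.write(f"{i + 1} {type_of[seq[i]]} {p[0]:.8f} {p[1]:.8f} {p[2]:.8f}\n")


def read_dump(path: str | Path) -> Trajectory:
    """Parse a LAMMPS-style text dump written by :func:`write_dump`."""
    traj = Trajectory()
    lines = Path(path).read_text().splitlines()
    i = 0
    while i < len(lines):
        assert lines[i].startswith("ITEM: TIMESTEP")
        t_fs = float(lines[i + 1])
        assert lines[i + 2].startswith("ITEM: NUMBER OF ATOMS")
        n = int(lines[i + 3])
        assert lines[i + 4].startswith("ITEM: BOX BOUNDS")
        box = np.empty(3)
        for d in range(3):
            lo, hi = map(float, lines[i + 5 + d].split())
            box[d] = hi - lo
        assert lines[i + 8].startswith("ITEM: ATOMS")
        pos = np.empty((n, 3))
        for k in range(n):
            parts = lines[i + 9 + k].split()
            idx = int(parts[0]) - 1
            pos[idx] = [float(parts[2]), float(parts[3]), float(parts[4])]
        traj.frames.append(Frame(time=t_fs / 1e6, positions=pos, box=box))
        i += 9 + n
    return traj
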