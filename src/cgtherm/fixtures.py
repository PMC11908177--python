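"""Synthetic parameter sets and ground-truth data generators.

Everything downstream (engine, cloud-point detection, binodal fitting,
scaling-exponent inversion) is tested against these generators in closed
loop: each generator records the parameters it used so the corresponding
analysis operation can be required to recover them.  The generated values
emulate the *schema* and statistical shape of real parameter tables, never
any particular published fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from cgtherm.constants import (
    AMINO_ACIDS,
    HYDROPHOBIC_RESIDUES,
    RESIDUE_CHARGES,
    RESIDUE_MASSES,
    T_REF,
)
from cgtherm.analysis import DensityProfile
from cgtherm.forcefield.parameters import (
    BondParams,
    ElectrostaticsParams,
    ForceFieldParameters,
    PairParams,
    ResidueParams,
    TempScalingParams,
)

ParamStyle = Literal["attractive", "repulsive_at_high_T", "neutral"]


@dataclass
class FixtureSpec:
    seed: int
    kind: str
    ground_truth: dict = field(default_factory=dict)


def make_param_set(
    seed: int = 0,
    style: ParamStyle = "neutral",
    charges: bool = True,
    yukawa_cutoff: float = 25.0,
    ionic_species: tuple[tuple[int, float], ...] = ((1, 0.15), (-1, 0.15)),
) -> ForceFieldParameters:
    """Complete synthetic 20-residue parameter set.

    Styles
    ------
    neutral
        All scaling weights zero: well depths are temperature independent.
    attractive
        Temperature independent but with uniformly deep wells, so chains
        condense readily at any temperature.
    repulsive_at_high_T
        Hydrophobic-pair well depths decrease linearly with temperature and
        change sign between the reference temperature and ~360 K, guaranteeing
        the repulsive branch engages at high temperature.
    """
    rng = np.random.default_rng(seed)
    residues = {}
    for code in AMINO_ACIDS:
        eps = float(rng.uniform(0.15, 0.45))
        if style == "attractive":
            eps = float(rng.uniform(0.8, 1.2))
        residues[code] = ResidueParams(
            code=code,
            mass=RESIDUE_MASSES[code],
            charge=RESIDUE_CHARGES[code] if charges else 0.0,
            sigma=float(rng.uniform(4.5, 6.5)),
            epsilon_mpipi=eps,
        )

    pairs = {}
    codes = sorted(AMINO_ACIDS)
    for a in codes:
        for b in codes:
            if a > b:
                continue
            ra, rb = residues[a], residues[b]
            sigma_ij = 0.5 * (ra.sigma + rb.sigma)
            eps_ij = float(np.sqrt(ra.epsilon_mpipi * rb.epsilon_mpipi))
            mu_ij = float(rng.integers(1, 4))
            pairs[(a, b)] = PairParams(
                sigma_ij=sigma_ij, epsilon_ij_ref=eps_ij, mu_ij=mu_ij, nu_ij=1.0
            )

    scaling = {}
    for code in AMINO_ACIDS:
        if style in ("neutral", "attractive") or code not in HYDROPHOBIC_RESIDUES:
            scaling[code] = TempScalingParams()
            continue
        # alpha * b * (T - T_ref) drives eps_ij from positive at T_ref to
        # negative at 360 K: slope ~ -eps/30 per kelvin of self depth.
        eps_self = residues[code].epsilon_mpipi
        slope = -eps_self / 30.0 * float(rng.uniform(0.9, 1.1))
        scaling[code] = TempScalingParams(a=0.0, b=slope, c=0.0, alpha=1.0)

    electrostatics = ElectrostaticsParams(
        ionic_species=ionic_species if charges else (),
        yukawa_cutoff=yukawa_cutoff,
    )
    return ForceFieldParameters(
        residues=residues,
        scaling=scaling,
        pairs=pairs,
        electrostatics=electrostatics,
        bond=BondParams(),
        t_ref=T_REF,
    )


def make_profiles(
    seed: int,
    t_cloud: float,
    grid,
    n_frames: int = 20,
    n_bins: int = 40,
    box_length: float = 400.0,
    base_density: float = 0.02,
    spike_ratio: float = 20.0,
    noise: float = 0.0,
) -> dict[float, list[DensityProfile]]:
    """Flat profiles below ``t_cloud``; a Gaussian slab spike at and above.

    Returns ``{T: [DensityProfile, ...]}`` ordered by ascending temperature;
    ``t_cloud`` must lie inside the grid.
    """
    grid = sorted(float(t) for t in grid)
    if not (grid[0] <= t_cloud <= grid[-1]):
        raise ValueError("t_cloud must lie inside the temperature grid")
    rng = np.random.default_rng(seed)
    z = (np.arange(n_bins) + 0.5) * box_length / n_bins
    out: dict[float, list[DensityProfile]] = {}
    for T in grid:
        frames = []
        for k in range(n_frames):
            if T >= t_cloud:
                center = box_length / 2.0
                width = box_length / 25.0
                spike = np.exp(-0.5 * ((z - center) / width) ** 2)
                # scale so max bin >= spike_ratio * mean density
                rho = base_density * (1.0 + spike_ratio * spike * n_bins / max(spike.sum(), 1.0))
            else:
                rho = np.full(n_bins, base_density)
            if noise > 0:
                rho = np.clip(rho * (1.0 + rng.normal(0, noise, n_bins)), 0.0, None)
            frames.append(
                DensityProfile(z.copy(), rho, temperature=T, frame_time=float(k))
            )
        out[T] = frames
    return out


def make_binodal(
    seed: int,
    t_c: float = 300.0,
    rho_c: float = 0.35,
    amplitude: float = 0.08,
    slope: float = 0.002,
    beta: float = 0.325,
    noise: float = 0.0,
    temperatures=None,
    lcst: bool = True,
):
    """Coexistence points generated from the exact laws used by the fitter.

    Returns a list of (T, rho_dilute, rho_dense).  Multiplicative noise of
    relative magnitude ``noise`` is applied to each density independently.
    """
    if temperatures is None:
        temperatures = t_c + (np.arange(1, 11) * 4.0) * (1.0 if lcst else -1.0)
    rng = np.random.default_rng(seed)
    pts = []
    for T in np.sort(np.asarray(temperatures, dtype=float)):
        dt = (T - t_c) if lcst else (t_c - T)
        if dt < 0:
            raise ValueError("temperatures must lie on the two-phase side of t_c")
        gap = amplitude * dt**beta
        mid = rho_c + slope * (T - t_c)
        lo = mid - gap / 2.0
        hi = mid + gap / 2.0
        if noise > 0:
            lo *= 1.0 + rng.normal(0, noise)
            hi *= 1.0 + rng.normal(0, noise)
        lo = max(lo, 1e-6)
        hi = max(hi, lo + 1e-6)
        pts.append((float(T), float(lo), float(hi)))
    return pts


def make_rg_series(
    seed: int,
    n_bonds: int = 100,
    t_theta: float = 320.0,
    temperatures=None,
    nu_hot: float = 0.35,
    nu_cold: float = 0.65,
    noise: float = 0.0,
    n_samples: int = 30,
    b: float = 5.5,
    gamma: float = 1.1615,
):
    """Rg samples per temperature for a chain whose nu(T) falls linearly
    through 0.5 at ``t_theta`` (LCST orientation).

    Returns (temperatures, {T: rg_samples}, ground_truth_nu_by_T).
    """
    from cgtherm.analysis import flory_forward

    if temperatures is None:
        temperatures = np.arange(280.0, 371.0, 10.0)
    temperatures = np.sort(np.asarray(temperatures, dtype=float))
    rng = np.random.default_rng(seed)
    t_lo, t_hi = temperatures[0], temperatures[-1]
    nus = nu_cold + (nu_hot - nu_cold) * (temperatures - t_lo) / (t_hi - t_lo)
    # shift/scale so nu = 0.5 exactly at t_theta
    nus = 0.5 + (nu_hot - nu_cold) / (t_hi - t_lo) * (temperatures - t_theta)
    samples = {}
    truth = {}
    for T, nu in zip(temperatures, nus):
        rg = flory_forward(float(nu), n_bonds, b, gamma)
        draw = rg * (1.0 + rng.normal(0, noise, n_samples)) if noise > 0 else np.full(n_samples, rg)
        samples[float(T)] = draw
        truth[float(T)] = float(nu)
    return temperatures, samples, truth


def make_absorbance_curve(
    seed: int,
    t_cloud: float = 312.0,
    temperatures=None,
    sharpness: float = 1.0,
    noise: float = 0.0,
):
    """Sigmoidal absorbance curve crossing 0.301 at ``t_cloud``."""
    if temperatures is None:
        temperatures = np.arange(290.0, 331.0, 1.0)
    temperatures = np.sort(np.asarray(temperatures, dtype=float))
    rng = np.random.default_rng(seed)
    threshold = -np.log10(0.5)
    amplitude = 2.0 * threshold  # sigmoid midpoint sits exactly at 0.301
    curve = amplitude / (1.0 + np.exp(-sharpness * (temperatures - t_cloud)))
    if noise > 0:
        curve = np.clip(curve + rng.normal(0, noise, len(curve)), 0.0, None)
    return temperatures, curve
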