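"""Slab, cloud-point, binodal and single-chain scaling analysis.

Implements the finite-size cloud-point detector (spike criterion on z-density
profiles), coexistence-density extraction from slab profiles, critical-point
fitting with the laws of coexistence densities and rectilinear diameters,
radius-of-gyration series, the scaling-exponent solver, block averaging and
the absorbance cloud-point convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, least_squares

from cgtherm.constants import AVOGADRO
from cgtherm.forcefield.parameters import ForceFieldParameters
from cgtherm.system_builder import ChainTopology


class AnalysisError(ValueError):
    pass


# ------------------------------------------------------------- density profiles

@dataclass
class DensityProfile:
    """Mass density binned along one box axis at a single temperature."""

    bin_centers: np.ndarray  # angstrom
    mass_density: np.ndarray  # g/cm^3
    temperature: float = 0.0  # K
    frame_time: float = 0.0  # ns

    def __post_init__(self) -> None:
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        self.mass_density = np.asarray(self.mass_density, dtype=float)
        if self.bin_centers.shape != self.mass_density.shape:
            raise AnalysisError("bin_centers and mass_density shapes differ")

    @property
    def bin_width(self) -> float:
        return float(self.bin_centers[1] - self.bin_centers[0])


def density_profile(
    positions: np.ndarray,
    box: np.ndarray,
    masses: np.ndarray,
    axis: int = 2,
    bin_width: float = 5.0,
    temperature: float = 0.0,
    frame_time: float = 0.0,
) -> DensityProfile:
    """Mass-weighted histogram along ``axis`` converted to g/cm^3."""
    positions = np.asarray(positions, dtype=float)
    if positions.size == 0:
        raise AnalysisError("empty frame")
    box = np.asarray(box, dtype=float)
    length = box[axis]
    n_bins = max(int(round(length / bin_width)), 1)
    edges = np.linspace(0.0, length, n_bins + 1)
    coords = np.mod(positions[:, axis], length)
    hist, _ = np.histogram(coords, bins=edges, weights=masses)
    cross_section = float(np.prod(np.delete(box, axis)))
    bin_volume_cm3 = cross_section * (length / n_bins) * 1e-24
    density = hist / AVOGADRO / bin_volume_cm3
    centers = 0.5 * (edges[:-1] + edges[1:])
    return DensityProfile(centers, density, temperature=temperature, frame_time=frame_time)


def detect_cloud_point(
    profiles_by_temperature: dict[float, list[DensityProfile]],
    spike_ratio: float = 5.0,
    persistence: int = 10,
) -> float | None:
    """Lowest temperature with a sustained density spike, else None.

    A frame "spikes" when its maximum bin density is at least ``spike_ratio``
    times the overall mean density; the criterion must hold in at least
    ``persistence`` consecutive sampled frames.
    """
    temps = list(profiles_by_temperature.keys())
    if sorted(temps) != temps:
        raise AnalysisError("profiles must be sorted by ascending temperature")
    if len(temps) < 2:
        raise AnalysisError("need profiles at >= 2 temperatures")
    for T in temps:
        run = 0
        for prof in profiles_by_temperature[T]:
            mean = prof.mass_density.mean()
            spiked = mean > 0 and prof.mass_density.max() >= spike_ratio * mean
            run = run + 1 if spiked else 0
            if run >= persistence:
                return T
    return None


def coexistence_densities(
    profiles_at_T: list[DensityProfile],
    interface_exclusion: float = 10.0,
) -> tuple[float, float]:
    """(dilute, dense) phase densities in g/cm^3 from slab profiles.

    Profiles are averaged, recentred periodically on the dense phase, the
    slab extent located by half-max thresholding, and phase densities taken
    away from the interfaces by ``interface_exclusion`` angstrom.
    """
    if not profiles_at_T:
        raise AnalysisError("no profiles given")
    z = profiles_at_T[0].bin_centers
    length = z[-1] + 0.5 * profiles_at_T[0].bin_width
    rho = np.mean([p.mass_density for p in profiles_at_T], axis=0)
    if rho.max() <= 0:
        raise AnalysisError("empty density profile; no identifiable slab")

    # periodic centre of mass of the density
    theta = 2.0 * np.pi * z / length
    xc = np.sum(rho * np.cos(theta))
    yc = np.sum(rho * np.sin(theta))
    center = np.mod(np.arctan2(yc, xc), 2.0 * np.pi) / (2.0 * np.pi) * length

    dz = z - center
    dz -= np.round(dz / length) * length  # signed displacement in (-L/2, L/2]

    threshold = 0.5 * (rho.max() + rho.min())
    in_slab = rho >= threshold
    if not in_slab.any() or in_slab.all():
        raise AnalysisError("no identifiable slab (profile lacks contrast)")
    half_width = np.abs(dz[in_slab]).max()

    core = np.abs(dz) <= half_width - interface_exclusion
    far = np.abs(dz) >= half_width + interface_exclusion
    if not core.any() or not far.any():
        raise AnalysisError(
            "interface exclusion leaves no core or far-field bins; "
            "reduce interface_exclusion or use a longer box"
        )
    dense = float(rho[core].mean())
    dilute = float(rho[far].mean())
    return dilute, dense


# ------------------------------------------------------------------ binodal fit

@dataclass
class BinodalFit:
    """Coexistence points plus the fitted critical point."""

    temperatures: np.ndarray
    dilute_density: np.ndarray
    dense_density: np.ndarray
    t_c: float
    rho_c: float
    amplitude: float  # A of the coexistence-density law
    slope: float  # B of the rectilinear-diameter law
    exponent_beta: float
    fit_residual: float
    lcst: bool = True


def fit_binodal(
    coexistence_points,
    lcst: bool = True,
    beta: float = 0.325,
) -> BinodalFit:
    """Simultaneous fit of the coexistence-density and rectilinear-diameter laws.

    rho_dense - rho_dilute = A * |T - T_c|^beta
    (rho_dense + rho_dilute)/2 = rho_c + B * (T - T_c)

    ``coexistence_points`` is an iterable of (T, rho_dilute, rho_dense); the
    gap must widen above T_c for LCST data (below for UCST).
    """
    pts = np.asarray([(t, lo, hi) for t, lo, hi in coexistence_points], dtype=float)
    if pts.shape[0] < 4:
        raise AnalysisError("need coexistence data at >= 4 temperatures")
    T, lo, hi = pts[:, 0], pts[:, 1], pts[:, 2]
    if np.any(hi <= lo):
        raise AnalysisError("dense density must exceed dilute density at every T")
    gap = hi - lo
    mid = 0.5 * (hi + lo)
    sign = 1.0 if lcst else -1.0

    def residuals(params):
        t_c, rho_c, amp, slope = params
        dt = sign * (T - t_c)
        dt = np.where(dt > 0, dt, 0.0)
        r1 = amp * dt**beta - gap
        r2 = rho_c + slope * (T - t_c) - mid
        return np.concatenate([r1, r2])

    span = T.max() - T.min()
    t0 = (T.min() - 0.25 * span) if lcst else (T.max() + 0.25 * span)
    amp0 = gap.max() / max(span, 1e-6) ** beta
    slope0 = np.polyfit(T, mid, 1)[0]
    rho0 = float(np.mean(mid) - slope0 * (np.mean(T) - t0))
    if lcst:
        # critical point must lie at or below the coldest data point
        lower = [T.min() - 10 * span - 1.0, 0.0, 0.0, -np.inf]
        upper = [T.min() + 1e-9, np.inf, np.inf, np.inf]
    else:
        lower = [T.max() - 1e-9, 0.0, 0.0, -np.inf]
        upper = [T.max() + 10 * span + 1.0, np.inf, np.inf, np.inf]
    result = least_squares(
        residuals,
        x0=[t0, rho0, amp0, slope0],
        bounds=(lower, upper),
        method="trf",
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
    )
    if not result.success:
        raise AnalysisError(f"binodal fit failed to converge: {result.message}")
    t_c, rho_c, amp, slope = result.x
    return BinodalFit(
        temperatures=T,
        dilute_density=lo,
        dense_density=hi,
        t_c=float(t_c),
        rho_c=float(rho_c),
        amplitude=float(amp),
        slope=float(slope),
        exponent_beta=beta,
        fit_residual=float(np.sum(result.fun**2)),
        lcst=lcst,
    )


# ------------------------------------------------- chain size and Flory scaling

def unwrap_chain(positions: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Undo periodic wrapping along a linear chain (consecutive beads)."""
    out = np.array(positions, dtype=float)
    for i in range(1, out.shape[0]):
        d = out[i] - out[i - 1]
        out[i] -= np.round(d / box) * box
    return out


def radius_of_gyration(
    positions: np.ndarray,
    masses: np.ndarray,
    box: np.ndarray | None = None,
    max_bond: float | None = None,
) -> float:
    """Mass-weighted radius of gyration of one chain, in angstrom.

    If ``box`` is given the chain is unwrapped first; ``max_bond`` enables a
    sanity check that unwrapping succeeded.
    """
    pos = np.asarray(positions, dtype=float)
    if box is not None:
        pos = unwrap_chain(pos, np.asarray(box, dtype=float))
    if max_bond is not None and pos.shape[0] > 1:
        bonds = np.linalg.norm(np.diff(pos, axis=0), axis=1)
        if np.any(bonds > max_bond):
            raise AnalysisError(
                f"bond length {bonds.max():.2f} A exceeds {max_bond:.2f} A; "
                "periodic wrap artefact suspected"
            )
    m = np.asarray(masses, dtype=float)
    com = np.average(pos, axis=0, weights=m)
    sq = np.sum((pos - com) ** 2, axis=1)
    return float(np.sqrt(np.average(sq, weights=m)))


@dataclass
class FlorySeries:
    """nu(T) series derived from mean radii of gyration."""

    temperatures: np.ndarray
    mean_rg: np.ndarray
    stderr_rg: np.ndarray
    nu: np.ndarray
    stderr_nu: np.ndarray
    n_bonds: int
    b: float = 5.5
    gamma: float = 1.1615


def flory_forward(nu: float, n_bonds: int, b: float = 5.5, gamma: float = 1.1615) -> float:
    """Radius of gyration predicted for scaling exponent nu.

    S = sqrt( gamma (gamma+1) / (2 (gamma+2 nu)(gamma+2 nu+1)) ) * b * N^nu
    """
    pref = np.sqrt(gamma * (gamma + 1.0) / (2.0 * (gamma + 2.0 * nu) * (gamma + 2.0 * nu + 1.0)))
    return float(pref * b * n_bonds**nu)


def flory_nu(
    mean_rg: float,
    n_bonds: int,
    b: float = 5.5,
    gamma: float = 1.1615,
    bracket: tuple[float, float] = (0.05, 0.95),
) -> float:
    """Invert :func:`flory_forward` for nu on the bracket."""
    if mean_rg <= 0:
        raise AnalysisError("mean_rg must be positive")
    if n_bonds < 1:
        raise AnalysisError("n_bonds must be >= 1")
    lo, hi = bracket

    def f(nu):
        return flory_forward(nu, n_bonds, b, gamma) - mean_rg

    flo, fhi = f(lo), f(hi)
    if flo * fhi > 0:
        raise AnalysisError(
            f"no scaling exponent in ({lo}, {hi}) reproduces Rg = {mean_rg:.3f} A "
            f"for N = {n_bonds}"
        )
    return float(brentq(f, lo, hi, xtol=1e-12))


def flory_series(
    temperatures,
    rg_samples_by_T,
    n_bonds: int,
    b: float = 5.5,
    gamma: float = 1.1615,
    n_blocks: int = 3,
) -> FlorySeries:
    """Block-averaged Rg and nu versus temperature."""
    temps = np.asarray(list(temperatures), dtype=float)
    means, errs, nus, nu_errs = [], [], [], []
    for T in temps:
        samples = np.asarray(rg_samples_by_T[float(T)], dtype=float)
        mean, err = block_errors(samples, n_blocks=n_blocks)
        means.append(mean)
        errs.append(err)
        nus.append(flory_nu(mean, n_bonds, b, gamma))
        # first-order error propagation through the inversion
        h = max(err, 1e-9)
        try:
            nu_hi = flory_nu(mean + h, n_bonds, b, gamma)
            nu_lo = flory_nu(max(mean - h, 1e-9), n_bonds, b, gamma)
            nu_errs.append(abs(nu_hi - nu_lo) / 2.0)
        except AnalysisError:
            nu_errs.append(np.nan)
    return FlorySeries(
        temperatures=temps,
        mean_rg=np.asarray(means),
        stderr_rg=np.asarray(errs),
        nu=np.asarray(nus),
        stderr_nu=np.asarray(nu_errs),
        n_bonds=n_bonds,
        b=b,
        gamma=gamma,
    )


def coil_globule_temperature(series: FlorySeries, threshold: float = 0.5) -> float | None:
    """Temperature where nu crosses ``threshold``, by linear interpolation.

    Returns the first crossing in ascending temperature (with a warning when
    several exist); None when nu never crosses, in which case the sign of
    nu - threshold is reported in the warning.
    """
    T = series.temperatures
    d = series.nu - threshold
    crossings = []
    for i in range(len(T) - 1):
        if d[i] == 0.0:
            crossings.append(float(T[i]))
        elif d[i] * d[i + 1] < 0:
            frac = d[i] / (d[i] - d[i + 1])
            crossings.append(float(T[i] + frac * (T[i + 1] - T[i])))
    if d[-1] == 0.0:
        crossings.append(float(T[-1]))
    if not crossings:
        side = "above" if np.all(d > 0) else "below" if np.all(d < 0) else "mixed"
        warnings.warn(f"nu - {threshold} never crosses zero (all {side})", stacklevel=2)
        return None
    if len(crossings) > 1:
        warnings.warn(
            f"multiple nu = {threshold} crossings at {crossings}; using the first",
            stacklevel=2,
        )
    return crossings[0]


# ------------------------------------------------------------------ statistics

def block_errors(samples, n_blocks: int = 3) -> tuple[float, float]:
    """Mean and standard error over contiguous block means.

    Blocks are equal-sized; any remainder goes to the last block.
    """
    x = np.asarray(list(samples), dtype=float)
    if len(x) < n_blocks:
        raise AnalysisError(f"need at least {n_blocks} samples, got {len(x)}")
    size = len(x) // n_blocks
    means = []
    for k in range(n_blocks):
        start = k * size
        end = (k + 1) * size if k < n_blocks - 1 else len(x)
        means.append(x[start:end].mean())
    means = np.asarray(means)
    overall = float(means.mean())
    stderr = float(means.std(ddof=1) / np.sqrt(n_blocks)) if n_blocks > 1 else 0.0
    return overall, stderr


def absorbance_cloud_point(
    temperatures, absorbances, threshold: float = -np.log10(0.5)
) -> float | None:
    """First temperature where absorbance crosses 0.301 (transmittance 1/2)."""
    T = np.asarray(list(temperatures), dtype=float)
    A = np.asarray(list(absorbances), dtype=float)
    order = np.argsort(T)
    T, A = T[order], A[order]
    d = A - threshold
    for i in range(len(T) - 1):
        if d[i] == 0.0:
            return float(T[i])
        if d[i] * d[i + 1] < 0:
            frac = d[i] / (d[i] - d[i + 1])
            return float(T[i] + frac * (T[i + 1] - T[i]))
    if d[-1] == 0.0:
        return float(T[-1])
    return None


# --------------------------------------------------------------- trajectory R_g

def rg_samples(traj, chain: ChainTopology, ff: ForceFieldParameters) -> np.ndarray:
    """Radius-of-gyration time series for one chain over a trajectory."""
    masses = np.array([ff.residue(c).mass for c in chain.sequence])
    out = []
    for frame in traj:
        pos = frame.positions[chain.indices]
        out.append(radius_of_gyration(pos, masses, box=frame.box))
    return np.asarray(out)
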