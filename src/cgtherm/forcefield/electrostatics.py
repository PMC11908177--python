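"""Temperature-dependent dielectric, Debye screening and Yukawa terms."""

from __future__ import annotations

import numpy as np

from cgtherm import constants
from cgtherm.constants import (
    AVOGADRO,
    BOLTZMANN_SI,
    COULOMB,
    ELEMENTARY_CHARGE,
    T_MAX,
    T_MIN,
    VACUUM_PERMITTIVITY,
)
from cgtherm.forcefield.parameters import ElectrostaticsParams, ForceFieldError


class TemperatureRangeError(ValueError):
    """Temperature outside the liquid-water validity window [273, 373] K."""


def _check_temperature(T: float) -> None:
    if not (T_MIN <= T <= T_MAX):
        raise TemperatureRangeError(
            f"T = {T} K outside model validity window [{T_MIN}, {T_MAX}] K"
        )


def water_density(T):
    """Density of air-free liquid water in g/cm^3 (Kell 1975 polynomial).

    Parameters
    ----------
    T : float or array
        Temperature in kelvin, restricted to [273, 373].
    """
    scalar = np.isscalar(T)
    T = np.asarray(T, dtype=float)
    if np.any(T < T_MIN) or np.any(T > T_MAX):
        raise TemperatureRangeError(
            f"temperature outside model validity window [{T_MIN}, {T_MAX}] K"
        )
    t = T - 273.15
    num = np.polynomial.polynomial.polyval(t, constants.KELL_NUMERATOR)
    rho = num / (1.0 + constants.KELL_DENOMINATOR_B * t) / 1000.0  # kg/m^3 -> g/cm^3
    return float(rho) if scalar else rho


def dielectric(T, d_coefficients=constants.DEFAULT_D_COEFFICIENTS):
    """Relative static dielectric constant eps(T) = 1 + rho_solv(T) * d(T).

    ``d(T) = d0 + d1*T`` is the linear solvent parameter; the defaults are a
    least-squares fit against an experimental water-dielectric table
    (see :func:`fit_d_coefficients`).
    """
    d0, d1 = d_coefficients
    eps = 1.0 + water_density(T) * (d0 + d1 * np.asarray(T, dtype=float))
    if np.any(np.asarray(eps) <= 0):
        raise ForceFieldError("dielectric constant must be positive; check d coefficients")
    return float(eps) if np.isscalar(T) else eps


def fit_d_coefficients(table=None):
    """Least-squares fit of (d0, d1) so that 1 + rho(T)(d0+d1*T) tracks ``table``.

    ``table`` is an (n, 2) array of (T kelvin, eps); defaults to the packaged
    experimental water table.  Returns ``(d0, d1)``.
    """
    if table is None:
        table = constants.WATER_DIELECTRIC_TABLE
    table = np.asarray(table, dtype=float)
    T, eps = table[:, 0], table[:, 1]
    rho = water_density(np.clip(T, T_MIN, T_MAX))
    y = (eps - 1.0) / rho
    design = np.column_stack([np.ones_like(T), T])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return float(coef[0]), float(coef[1])


def inverse_debye_length(T: float, electrostatics: ElectrostaticsParams) -> float:
    """Inverse Debye length kappa in 1/angstrom.

    kappa^2 = e^2 / (eps(T) eps0 kB T) * sum_j z_j^2 c_j with concentrations
    in mol/L converted to number densities.
    """
    _check_temperature(T)
    ionic_term = electrostatics.ionic_strength_term()  # mol/L
    if ionic_term == 0.0:
        return 0.0
    eps_r = dielectric(T, electrostatics.d_coefficients)
    number_density = ionic_term * 1000.0 * AVOGADRO  # ions/m^3
    kappa_sq_m = (
        ELEMENTARY_CHARGE**2
        / (eps_r * VACUUM_PERMITTIVITY * BOLTZMANN_SI * T)
        * number_density
    )
    return float(np.sqrt(kappa_sq_m) * 1e-10)  # 1/m -> 1/A


def _yukawa_raw(r, q_i, q_j, eps_r, kappa):
    return COULOMB * q_i * q_j * np.exp(-kappa * np.asarray(r, dtype=float)) / (eps_r * np.asarray(r, dtype=float))


def yukawa_energy(r, q_i: float, q_j: float, T: float, electrostatics: ElectrostaticsParams):
    """Screened-Coulomb pair energy in kcal/mol; zero beyond the cutoff.

    With ``shift_at_cutoff`` (default) the energy is shifted so it is exactly
    zero at the cutoff, keeping the potential continuous there.
    """
    scalar = np.isscalar(r)
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ZeroDivisionError("Yukawa energy singular at r <= 0")
    if q_i == 0.0 or q_j == 0.0:
        out = np.zeros_like(r)
        return float(out) if scalar else out
    _check_temperature(T)
    eps_r = dielectric(T, electrostatics.d_coefficients)
    kappa = inverse_debye_length(T, electrostatics)
    rc = electrostatics.yukawa_cutoff
    u = _yukawa_raw(r, q_i, q_j, eps_r, kappa)
    if electrostatics.shift_at_cutoff:
        u = u - _yukawa_raw(rc, q_i, q_j, eps_r, kappa)
    u = np.where(r >= rc, 0.0, u)
    return float(u) if scalar else u


def yukawa_force(r, q_i: float, q_j: float, T: float, electrostatics: ElectrostaticsParams):
    """Radial force -dU/dr of the (unshifted slope) Yukawa term, kcal/(mol A)."""
    scalar = np.isscalar(r)
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ZeroDivisionError("Yukawa force singular at r <= 0")
    if q_i == 0.0 or q_j == 0.0:
        out = np.zeros_like(r)
        return float(out) if scalar else out
    _check_temperature(T)
    eps_r = dielectric(T, electrostatics.d_coefficients)
    kappa = inverse_debye_length(T, electrostatics)
    rc = electrostatics.yukawa_cutoff
    u = _yukawa_raw(r, q_i, q_j, eps_r, kappa)
    f = u * (kappa + 1.0 / r)  # -d/dr [C exp(-kr)/r] = C exp(-kr)(k/r + 1/r^2)
    f = np.where(r >= rc, 0.0, f)
    return float(f) if scalar else f
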