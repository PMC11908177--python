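"""Wang-Frenkel pair potential, its repulsive variant, and the dispatcher.

The attractive branch is the canonical finite-range Wang-Frenkel form

    phi(r) = eps * alpha * ((sigma/r)^(2mu) - 1) * ((R/r)^(2mu) - 1)^(2nu)

for r < R (zero beyond), with alpha normalised so the well depth at the
minimum r* equals eps exactly.  When the temperature-scaled well depth of a
pair turns negative the short-range interaction switches to a WCA-style
purely repulsive truncation that preserves the bead diameter:

    phi_rep(r) = -phi(r; eps) - eps   for r < r*,   0 otherwise   (eps < 0)

which is positive, continuous (and exactly zero) at r*, and diverges as
r -> 0.
"""

from __future__ import annotations

import math

from cgtherm.forcefield.parameters import (
    ForceFieldError,
    ForceFieldParameters,
    PairParams,
    TempScalingParams,
)


def wf_alpha(pair: PairParams) -> float:
    """Normalisation constant alpha_ij of the Wang-Frenkel potential.

    Canonical closed form guaranteeing phi(r*) = -eps.
    """
    mu, nu = pair.mu_ij, pair.nu_ij
    ratio = (pair.r_cut / pair.sigma_ij) ** (2.0 * mu)
    return 2.0 * nu * ratio * ((1.0 + 2.0 * nu) / (2.0 * nu * (ratio - 1.0))) ** (
        2.0 * nu + 1.0
    )


def wf_r_star(pair: PairParams) -> float:
    """Location of the Wang-Frenkel minimum, sigma_ij < r* < r_cut."""
    mu, nu = pair.mu_ij, pair.nu_ij
    ratio = (pair.r_cut / pair.sigma_ij) ** (2.0 * mu)
    return pair.r_cut * ((1.0 + 2.0 * nu) / (1.0 + 2.0 * nu * ratio)) ** (
        1.0 / (2.0 * mu)
    )


def _wf_shape(r: float, pair: PairParams) -> float:
    """alpha * ((sigma/r)^2mu - 1) * ((R/r)^2mu - 1)^2nu, without eps."""
    mu, nu = pair.mu_ij, pair.nu_ij
    a = (pair.sigma_ij / r) ** (2.0 * mu) - 1.0
    b = (pair.r_cut / r) ** (2.0 * mu) - 1.0
    return wf_alpha(pair) * a * b ** (2.0 * nu)


def _wf_shape_deriv(r: float, pair: PairParams) -> float:
    """d/dr of :func:`_wf_shape`."""
    mu, nu = pair.mu_ij, pair.nu_ij
    sig_t = (pair.sigma_ij / r) ** (2.0 * mu)
    cut_t = (pair.r_cut / r) ** (2.0 * mu)
    a = sig_t - 1.0
    b = cut_t - 1.0
    da = -2.0 * mu * sig_t / r
    db = -2.0 * mu * cut_t / r
    return wf_alpha(pair) * (da * b ** (2.0 * nu) + a * 2.0 * nu * b ** (2.0 * nu - 1.0) * db)


def wf_energy(r: float, pair: PairParams, epsilon: float) -> float:
    """Attractive-branch Wang-Frenkel energy, kcal/mol; zero for r >= r_cut."""
    if r <= 0:
        raise ZeroDivisionError("Wang-Frenkel energy undefined at r <= 0")
    if epsilon <= 0:
        raise ForceFieldError(
            "wf_energy requires epsilon > 0; route non-positive well depths "
            "to wf_repulsive_energy"
        )
    if r >= pair.r_cut:
        return 0.0
    return epsilon * _wf_shape(r, pair)


def wf_force(r: float, pair: PairParams, epsilon: float) -> float:
    """-dU/dr of :func:`wf_energy`, kcal/(mol A)."""
    if r <= 0:
        raise ZeroDivisionError("Wang-Frenkel force undefined at r <= 0")
    if r >= pair.r_cut:
        return 0.0
    return -epsilon * _wf_shape_deriv(r, pair)


def wf_repulsive_energy(r: float, pair: PairParams, epsilon: float) -> float:
    """Purely repulsive WCA-style variant for negative well depths.

    Requires ``epsilon < 0``; zero for r >= r*, positive and monotonically
    increasing toward small r below it.
    """
    if epsilon >= 0:
        raise ForceFieldError("wf_repulsive_energy requires epsilon < 0")
    if r <= 0:
        raise ZeroDivisionError("repulsive energy undefined at r <= 0")
    r_star = wf_r_star(pair)
    if r >= r_star:
        return 0.0
    return -epsilon * _wf_shape(r, pair) - epsilon


def wf_repulsive_force(r: float, pair: PairParams, epsilon: float) -> float:
    """-dU/dr of :func:`wf_repulsive_energy`."""
    if epsilon >= 0:
        raise ForceFieldError("wf_repulsive_force requires epsilon < 0")
    if r <= 0:
        raise ZeroDivisionError("repulsive force undefined at r <= 0")
    if r >= wf_r_star(pair):
        return 0.0
    return epsilon * _wf_shape_deriv(r, pair)


def mu_X(T: float, scaling: TempScalingParams) -> float:
    """Parabolic modulation mu(T) = a*T^2 + b*T + c, kcal/mol."""
    return scaling.a * T * T + scaling.b * T + scaling.c


def epsilon_ij(T: float, i: str, j: str, ff: ForceFieldParameters) -> float:
    """Temperature-scaled well depth for a pair containing a hydrophobic residue.

    eps_ij(T) = 0.5 [eps_ii + alpha_i (mu_i(T) - mu_i(T_ref))]
              + 0.5 [eps_jj + alpha_j (mu_j(T) - mu_j(T_ref))]

    where eps_ii, eps_jj are the parent-model self well depths.  The result
    may be negative, in which case the short-range interaction must be the
    repulsive variant.
    """
    if not ff.is_scaled_pair(i, j):
        raise ForceFieldError(
            f"pair ({i}, {j}) contains no hydrophobic residue; "
            "use the unscaled pair epsilon"
        )
    total = 0.0
    for code in (i, j):
        res = ff.residue(code)
        s = ff.scaling_for(code)
        total += 0.5 * (res.epsilon_mpipi + s.alpha * (mu_X(T, s) - mu_X(s.t_ref, s)))
    return total


def effective_epsilon(T: float, i: str, j: str, ff: ForceFieldParameters) -> float:
    """Well depth actually used at temperature T: scaled or parent value."""
    if ff.is_scaled_pair(i, j):
        return epsilon_ij(T, i, j, ff)
    return ff.pair(i, j).epsilon_ij_ref


def pair_energy(r: float, i: str, j: str, T: float, ff: ForceFieldParameters) -> float:
    """Total nonbonded pair energy: short-range branch plus electrostatics."""
    from cgtherm.forcefield.electrostatics import yukawa_energy

    pair = ff.pair(i, j)
    eps = effective_epsilon(T, i, j, ff)
    if eps > 0:
        u = wf_energy(r, pair, eps)
    elif eps < 0:
        u = wf_repulsive_energy(r, pair, eps)
    else:
        u = 0.0
    qi = ff.residue(i).charge
    qj = ff.residue(j).charge
    if qi != 0.0 and qj != 0.0:
        u += yukawa_energy(r, qi, qj, T, ff.electrostatics)
    return u


def pair_force(r: float, i: str, j: str, T: float, ff: ForceFieldParameters) -> float:
    """-dU/dr of :func:`pair_energy` at fixed temperature, kcal/(mol A)."""
    from cgtherm.forcefield.electrostatics import yukawa_force

    pair = ff.pair(i, j)
    eps = effective_epsilon(T, i, j, ff)
    if eps > 0:
        f = wf_force(r, pair, eps)
    elif eps < 0:
        f = wf_repulsive_force(r, pair, eps)
    else:
        f = 0.0
    qi = ff.residue(i).charge
    qj = ff.residue(j).charge
    if qi != 0.0 and qj != 0.0:
        f += yukawa_force(r, qi, qj, T, ff.electrostatics)
    return f


def numerical_r_star(pair: PairParams, tol_factor: float = 1e-10) -> float:
    """Bracketed numerical minimisation of the WF shape; dev/test oracle path."""
    from scipy.optimize import minimize_scalar

    res = minimize_scalar(
        lambda r: _wf_shape(r, pair),
        bounds=(pair.sigma_ij, pair.r_cut),
        method="bounded",
        options={"xatol": tol_factor * pair.sigma_ij},
    )
    return float(res.x)
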