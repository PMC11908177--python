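"""LAMMPS ``pair_style table`` export and re-import.

One table file is written per temperature; each residue pair gets one
section (keyword ``WF_<i>_<j>``) with ``N``, then ``index r energy force``
rows.  Energies/forces are the full nonbonded pair interaction (short-range
branch plus shifted Yukawa electrostatics) evaluated at that temperature, so
the exported tables are bit-reproducible against :func:`pair_energy`.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from cgtherm.forcefield.parameters import ForceFieldParameters
from cgtherm.forcefield.potentials import pair_energy, pair_force


def table_keyword(i: str, j: str) -> str:
    a, b = sorted((i, j))
    return f"WF_{a}_{b}"


def write_pair_table(
    path: str | Path,
    ff: ForceFieldParameters,
    T: float,
    n_points: int = 1001,
    r_inner_factor: float = 0.8,
    codes: str | None = None,
    fmt: str = "%.12g",
    r_fmt: str = "%.17g",
) -> dict[str, tuple[float, float]]:
    """Write one table file covering all pairs of ``codes`` at temperature T.

    The radial grid for each pair spans [r_inner_factor * sigma_ij, r_max]
    where r_max is the larger of the short-range cutoff and (for charged
    pairs) the Yukawa cutoff.  Returns {keyword: (min_energy, max_energy)}.
    """
    codes = sorted(set(codes or "".join(ff.residues)))
    extremes: dict[str, tuple[float, float]] = {}
    lines = [f"# pair tables at T = {T:.6g} K (r angstrom, E kcal/mol, F kcal/mol/angstrom)"]
    for a in codes:
        for b in codes:
            if a > b:
                continue
            pair = ff.pair(a, b)
            qa, qb = ff.residue(a).charge, ff.residue(b).charge
            r_max = pair.r_cut
            if qa != 0.0 and qb != 0.0:
                r_max = max(r_max, ff.electrostatics.yukawa_cutoff)
            r = np.linspace(r_inner_factor * pair.sigma_ij, r_max, n_points)
            e = np.array([pair_energy(x, a, b, T, ff) for x in r])
            f = np.array([pair_force(x, a, b, T, ff) for x in r])
            kw = table_keyword(a, b)
            extremes[kw] = (float(e.min()), float(e.max()))
            lines.append("")
            lines.append(kw)
            lines.append(f"N {n_points}")
            lines.append("")
            for k in range(n_points):
                lines.append(
                    f"{k + 1} {r_fmt % r[k]} {fmt % e[k]} {fmt % f[k]}"
                )
    Path(path).write_text("\n".join(lines) + "\n")
    return extremes


def read_pair_table(path: str | Path) -> dict[str, np.ndarray]:
    """Parse a table file back into {keyword: (N, 3) array of r, E, F}."""
    out: dict[str, np.ndarray] = {}
    lines = Path(path).read_text().splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if not line or line.startswith("#"):
            i += 1
            continue
        keyword = line
        i += 1
        n = None
        while i < len(lines):
            meta = lines[i].strip()
            i += 1
            if meta.startswith("N "):
                n = int(meta.split()[1])
            elif meta:
                break
            if n is not None:
                break
        if n is None:
            raise ValueError(f"table section {keyword!r} lacks an N line")
        while i < len(lines) and not lines[i].strip():
            i += 1
        rows = np.empty((n, 3))
        for k in range(n):
            parts = lines[i + k].split()
            rows[k] = [float(parts[1]), float(parts[2]), float(parts[3])]
        i += n
        out[keyword] = rows
    return out


INPUT_TEMPLATE = """\
# Coarse-grained slab run (real units); tables generated at T = {temperature} K
units real
atom_style full
boundary p p p

read_data {data_file}

bond_style harmonic
bond_coeff 1 {bond_k} {bond_r0}

pair_style table linear {n_points}
{pair_coeff_lines}

special_bonds lj/coul 0.0 1.0 1.0

velocity all create {temperature} {seed}
fix integ all langevin {temperature} {temperature} {damp_fs} {seed}
fix nve all nve
timestep {timestep}

dump traj all custom {dump_every} dump.lammpstrj id type x y z
run {n_steps}
"""


def write_input_script(
    path: str | Path,
    table_file: str,
    data_file: str,
    ff: ForceFieldParameters,
    temperature: float,
    codes: str,
    n_points: int = 1001,
    timestep: float = 10.0,
    damp_fs: float = 5000.0,
    n_steps: int = 1000000,
    dump_every: int = 100000,
    seed: int = 1,
) -> None:
    """Input-script template wiring the data file and pair tables together."""
    codes_sorted = sorted(set(codes))
    type_of = {c: k + 1 for k, c in enumerate(codes_sorted)}
    coeff_lines = []
    for a in codes_sorted:
        for b in codes_sorted:
            if a > b:
                continue
            coeff_lines.append(
                f"pair_coeff {type_of[a]} {type_of[b]} {table_file} {table_keyword(a, b)}"
            )
    Path(path).write_text(
        INPUT_TEMPLATE.format(
            temperature=temperature,
            data_file=data_file,
            bond_k=ff.bond.k,
            bond_r0=ff.bond.r0,
            n_points=n_points,
            pair_coeff_lines="\n".join(coeff_lines),
            damp_fs=damp_fs,
            timestep=timestep,
            n_steps=n_steps,
            dump_every=dump_every,
            seed=seed,
        )
    )
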