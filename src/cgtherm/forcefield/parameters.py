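"""Parameter containers and tabular parameter-file I/O.

A parameter set lives on disk as a JSON (or YAML) manifest pointing at three
CSV tables::

    manifest.json
      residues: residues.csv      # code,mass,charge,sigma,epsilon
      pairs: pairs.csv            # code_i,code_j,sigma,epsilon,mu,nu[,r_cut]
      scaling: scaling.csv        # code,a,b,c,alpha
      electrostatics: {...}       # inline
      t_ref: 298.15
      bond: {r0: 3.81, k: 8.03}

All energies are kcal/mol, distances angstrom, charges elementary charges.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from cgtherm import constants
from cgtherm.constants import AMINO_ACIDS, HYDROPHOBIC_RESIDUES, T_REF


class ForceFieldError(ValueError):
    """Invalid or incomplete force-field parameters."""


@dataclass(frozen=True)
class ResidueParams:
    """Per-residue bead constants."""

    code: str
    mass: float
    charge: float
    sigma: float
    epsilon_mpipi: float

    @property
    def is_hydrophobic(self) -> bool:
        return self.code in HYDROPHOBIC_RESIDUES

    def __post_init__(self) -> None:
        if len(self.code) != 1 or self.code not in AMINO_ACIDS:
            raise ForceFieldError(f"unknown residue code {self.code!r}")
        if self.mass <= 0:
            raise ForceFieldError(f"residue {self.code}: mass must be > 0")
        if self.sigma <= 0:
            raise ForceFieldError(f"residue {self.code}: sigma must be > 0")


@dataclass(frozen=True)
class TempScalingParams:
    """Coefficients of the parabolic well-depth modulation.

    mu(T) = a*T^2 + b*T + c, applied with weight ``alpha`` relative to the
    reference temperature ``t_ref``.
    """

    a: float = 0.0
    b: float = 0.0
    c: float = 0.0
    alpha: float = 0.0
    t_ref: float = T_REF

    def __post_init__(self) -> None:
        if not (273.0 <= self.t_ref <= 373.0):
            raise ForceFieldError(f"t_ref {self.t_ref} outside [273, 373] K")


@dataclass(frozen=True)
class PairParams:
    """Wang-Frenkel shape parameters for one unordered residue pair."""

    sigma_ij: float
    epsilon_ij_ref: float
    mu_ij: float = 1.0
    nu_ij: float = 1.0
    r_cut: float | None = None

    def __post_init__(self) -> None:
        if self.sigma_ij <= 0:
            raise ForceFieldError("sigma_ij must be > 0")
        if self.mu_ij < 1 or self.nu_ij < 1:
            raise ForceFieldError("WF shape exponents mu, nu must be >= 1")
        if self.r_cut is None:
            object.__setattr__(self, "r_cut", 3.0 * self.sigma_ij)
        elif self.r_cut <= self.sigma_ij:
            raise ForceFieldError("r_cut must exceed sigma_ij")


@dataclass(frozen=True)
class ElectrostaticsParams:
    """Ionic environment plus the dielectric model d(T) = d0 + d1*T."""

    ionic_species: tuple[tuple[int, float], ...] = ()
    d_coefficients: tuple[float, float] = constants.DEFAULT_D_COEFFICIENTS
    yukawa_cutoff: float = 35.0
    shift_at_cutoff: bool = True

    def __post_init__(self) -> None:
        species = tuple((int(z), float(c)) for z, c in self.ionic_species)
        object.__setattr__(self, "ionic_species", species)
        for z, c in species:
            if c < 0:
                raise ForceFieldError(f"negative ionic concentration {c}")
        d0, d1 = self.d_coefficients
        for t in (273.0, 373.0):
            if d0 + d1 * t <= 0:
                raise ForceFieldError("d(T) must stay positive on [273, 373] K")

    def ionic_strength_term(self) -> float:
        """sum_j z_j^2 c_j in mol/L."""
        return sum(z * z * c for z, c in self.ionic_species)


@dataclass
class BondParams:
    """Harmonic bond: U = k (r - r0)^2 with k in kcal/(mol A^2)."""

    r0: float = 3.81
    k: float = 9.6

    def __post_init__(self) -> None:
        if self.r0 <= 0 or self.k <= 0:
            raise ForceFieldError("bond r0 and k must be positive")


def _pair_key(i: str, j: str) -> tuple[str, str]:
    return (i, j) if i <= j else (j, i)


@dataclass
class ForceFieldParameters:
    """Complete parameter set over the 20-residue alphabet."""

    residues: dict[str, ResidueParams]
    scaling: dict[str, TempScalingParams]
    pairs: dict[tuple[str, str], PairParams]
    electrostatics: ElectrostaticsParams = field(default_factory=ElectrostaticsParams)
    bond: BondParams = field(default_factory=BondParams)
    t_ref: float = T_REF

    def __post_init__(self) -> None:
        self.pairs = {_pair_key(*k): v for k, v in self.pairs.items()}

    def residue(self, code: str) -> ResidueParams:
        try:
            return self.residues[code]
        except KeyError:
            raise ForceFieldError(f"no parameters for residue {code!r}") from None

    def pair(self, i: str, j: str) -> PairParams:
        try:
            return self.pairs[_pair_key(i, j)]
        except KeyError:
            raise ForceFieldError(f"no pair parameters for ({i}, {j})") from None

    def scaling_for(self, code: str) -> TempScalingParams:
        try:
            return self.scaling[code]
        except KeyError:
            raise ForceFieldError(f"no scaling coefficients for residue {code!r}") from None

    def is_scaled_pair(self, i: str, j: str) -> bool:
        """Temperature scaling applies iff the pair contains a hydrophobic residue."""
        return i in HYDROPHOBIC_RESIDUES or j in HYDROPHOBIC_RESIDUES

    def validate(self, sequence: str | None = None) -> None:
        """Check completeness (optionally for one sequence only)."""
        codes = sorted(set(sequence)) if sequence else list(AMINO_ACIDS)
        for c in codes:
            self.residue(c)
            self.scaling_for(c)
        for a in codes:
            for b in codes:
                self.pair(a, b)

    # ------------------------------------------------------------------ I/O
    def save(self, directory: str | Path, name: str = "forcefield") -> Path:
        """Write the three CSV tables plus a JSON manifest; return manifest path."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        res_rows = [
            {
                "code": r.code,
                "mass": r.mass,
                "charge": r.charge,
                "sigma": r.sigma,
                "epsilon": r.epsilon_mpipi,
            }
            for r in sorted(self.residues.values(), key=lambda r: r.code)
        ]
        pair_rows = [
            {
                "code_i": i,
                "code_j": j,
                "sigma": p.sigma_ij,
                "epsilon": p.epsilon_ij_ref,
                "mu": p.mu_ij,
                "nu": p.nu_ij,
                "r_cut": p.r_cut,
            }
            for (i, j), p in sorted(self.pairs.items())
        ]
        scale_rows = [
            {"code": c, "a": s.a, "b": s.b, "c": s.c, "alpha": s.alpha}
            for c, s in sorted(self.scaling.items())
        ]
        pd.DataFrame(res_rows).to_csv(directory / f"{name}_residues.csv", index=False, float_format="%.17g")
        pd.DataFrame(pair_rows).to_csv(directory / f"{name}_pairs.csv", index=False, float_format="%.17g")
        pd.DataFrame(scale_rows).to_csv(directory / f"{name}_scaling.csv", index=False, float_format="%.17g")
        manifest = {
            "residues": f"{name}_residues.csv",
            "pairs": f"{name}_pairs.csv",
            "scaling": f"{name}_scaling.csv",
            "electrostatics": {
                "ionic_species": [list(s) for s in self.electrostatics.ionic_species],
                "d_coefficients": list(self.electrostatics.d_coefficients),
                "yukawa_cutoff": self.electrostatics.yukawa_cutoff,
                "shift_at_cutoff": self.electrostatics.shift_at_cutoff,
            },
            "bond": {"r0": self.bond.r0, "k": self.bond.k},
            "t_ref": self.t_ref,
        }
        manifest_path = directory / f"{name}.json"
        manifest_path.write_text(json.dumps(manifest, indent=2))
        return manifest_path

    @classmethod
    def load(cls, manifest_path: str | Path) -> "ForceFieldParameters":
        manifest_path = Path(manifest_path)
        text = manifest_path.read_text()
        if manifest_path.suffix in (".yaml", ".yml"):
            import yaml

            manifest = yaml.safe_load(text)
        else:
            manifest = json.loads(text)
        base = manifest_path.parent
        res_df = pd.read_csv(base / manifest["residues"], float_precision="round_trip")
        pair_df = pd.read_csv(base / manifest["pairs"], float_precision="round_trip")
        scale_df = pd.read_csv(base / manifest["scaling"], float_precision="round_trip")
        t_ref = float(manifest.get("t_ref", T_REF))
        residues = {
            row.code: ResidueParams(
                code=row.code,
                mass=float(row.mass),
                charge=float(row.charge),
                sigma=float(row.sigma),
                epsilon_mpipi=float(row.epsilon),
            )
            for row in res_df.itertuples()
        }
        pairs = {}
        for row in pair_df.itertuples():
            r_cut = float(row.r_cut) if "r_cut" in pair_df.columns and not math.isnan(row.r_cut) else None
            pairs[(row.code_i, row.code_j)] = PairParams(
                sigma_ij=float(row.sigma),
                epsilon_ij_ref=float(row.epsilon),
                mu_ij=float(row.mu),
                nu_ij=float(row.nu),
                r_cut=r_cut,
            )
        scaling = {
            row.code: TempScalingParams(
                a=float(row.a), b=float(row.b), c=float(row.c),
                alpha=float(row.alpha), t_ref=t_ref,
            )
            for row in scale_df.itertuples()
        }
        es = manifest.get("electrostatics", {})
        electrostatics = ElectrostaticsParams(
            ionic_species=tuple((int(z), float(c)) for z, c in es.get("ionic_species", ())),
            d_coefficients=tuple(es.get("d_coefficients", constants.DEFAULT_D_COEFFICIENTS)),
            yukawa_cutoff=float(es.get("yukawa_cutoff", 35.0)),
            shift_at_cutoff=bool(es.get("shift_at_cutoff", True)),
        )
        bond_cfg = manifest.get("bond", {})
        bond = BondParams(r0=float(bond_cfg.get("r0", 3.81)), k=float(bond_cfg.get("k", 9.6)))
        return cls(
            residues=residues,
            scaling=scaling,
            pairs=pairs,
            electrostatics=electrostatics,
            bond=bond,
            t_ref=t_ref,
        )
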