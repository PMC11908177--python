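"""Build simulable bead-chain systems: FASTA input, chain placement,
slab construction for finite-size cloud-point runs, snapshot output.

Conventions: orthorhombic periodic box with origin at the corner, lengths in
angstrom; ``z`` is the slab long axis; beads are ordered contiguously per
chain so bonded pairs are always consecutive indices.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from cgtherm.constants import AMINO_ACIDS, AVOGADRO
from cgtherm.forcefield.parameters import ForceFieldParameters


class SequenceError(ValueError):
    """Malformed FASTA record or unknown residue code."""


class GeometryError(ValueError):
    """Infeasible box or slab geometry."""


@dataclass
class ChainTopology:
    """One linear bead chain: sequence plus harmonic-bond bookkeeping."""

    sequence: str
    first_index: int
    bond_r0: float = 3.81
    bond_k: float = 9.6

    def __post_init__(self) -> None:
        bad = set(self.sequence) - set(AMINO_ACIDS)
        if bad:
            raise SequenceError(f"unknown residue codes: {sorted(bad)}")
        if not self.sequence:
            raise SequenceError("empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def indices(self) -> np.ndarray:
        return np.arange(self.first_index, self.first_index + len(self.sequence))

    @property
    def bonds(self) -> np.ndarray:
        """(n-1, 2) consecutive bead-index pairs."""
        idx = self.indices
        return np.column_stack([idx[:-1], idx[1:]])


@dataclass
class ParticleSystem:
    """Beads + chains + periodic box; the simulable state."""

    positions: np.ndarray  # (N, 3) angstrom
    velocities: np.ndarray  # (N, 3) angstrom/fs
    chains: list[ChainTopology]
    box: np.ndarray  # (3,) lengths, angstrom
    temperature: float = 300.0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.velocities = np.asarray(self.velocities, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        n = sum(len(c) for c in self.chains)
        if self.positions.shape != (n, 3):
            raise GeometryError(
                f"positions shape {self.positions.shape} inconsistent with "
                f"{n} beads in {len(self.chains)} chains"
            )
        if self.velocities.shape != self.positions.shape:
            raise GeometryError("velocities shape mismatch")
        if np.any(self.box <= 0):
            raise GeometryError("box lengths must be positive")

    @property
    def n_beads(self) -> int:
        return self.positions.shape[0]

    @property
    def residue_codes(self) -> str:
        return "".join(c.sequence for c in self.chains)

    def masses(self, ff: ForceFieldParameters) -> np.ndarray:
        return np.array([ff.residue(c).mass for c in self.residue_codes])

    def total_mass(self, ff: ForceFieldParameters) -> float:
        return float(self.masses(ff).sum())

    def mass_density(self, ff: ForceFieldParameters) -> float:
        """Overall mass density in g/cm^3."""
        volume_cm3 = float(np.prod(self.box)) * 1e-24
        return self.total_mass(ff) / AVOGADRO / volume_cm3

    def bonds(self) -> np.ndarray:
        if not self.chains:
            return np.zeros((0, 2), dtype=int)
        return np.vstack([c.bonds for c in self.chains])

    def molecule_ids(self) -> np.ndarray:
        out = np.empty(self.n_beads, dtype=np.int64)
        for m, c in enumerate(self.chains):
            out[c.indices] = m
        return out

    def wrap(self) -> None:
        """Wrap all positions into [0, box)."""
        self.positions -= np.floor(self.positions / self.box) * self.box

    def copy(self) -> "ParticleSystem":
        return ParticleSystem(
            positions=self.positions.copy(),
            velocities=self.velocities.copy(),
            chains=list(self.chains),
            box=self.box.copy(),
            temperature=self.temperature,
        )


# ---------------------------------------------------------------- FASTA I/O

def read_fasta(path: str | Path | io.TextIOBase) -> list[str]:
    """Read FASTA records as uppercase one-letter sequences, in file order."""
    if isinstance(path, io.TextIOBase):
        text = path.read()
    else:
        text = Path(path).read_text()
    sequences: list[str] = []
    current: list[str] | None = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            if current is not None:
                sequences.append("".join(current))
            current = []
        else:
            if current is None:
                raise SequenceError(f"line {lineno}: sequence data before any header")
            current.append(line.upper())
    if current is not None:
        sequences.append("".join(current))
    if not sequences:
        warnings.warn("empty FASTA input", stacklevel=2)
        return []
    for seq in sequences:
        if not seq:
            raise SequenceError("FASTA record with empty sequence")
        bad = set(seq) - set(AMINO_ACIDS)
        if bad:
            raise SequenceError(f"unknown residue codes {sorted(bad)}")
    return sequences


def write_fasta(path: str | Path, sequences: list[str], width: int = 60) -> None:
    with open(path, "w") as fh:
        for k, seq in enumerate(sequences):
            fh.write(f">seq{k}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ------------------------------------------------------------- construction

def replicate_count(sequence_length: int) -> int:
    """Number of chain replicates for slab runs: 64 below 190 residues, else 27."""
    if sequence_length < 1:
        raise SequenceError("sequence length must be >= 1")
    return 64 if sequence_length < 190 else 27


def _max_sigma(ff: ForceFieldParameters, sequence: str) -> float:
    codes = sorted(set(sequence))
    return max(ff.pair(a, b).sigma_ij for a in codes for b in codes)


def _random_walk(
    n: int,
    r0: float,
    rng: np.random.Generator,
    compact: float = 0.0,
    min_sep: float | None = None,
) -> np.ndarray:
    """Self-avoiding-ish random walk with fixed bond length r0.

    ``compact`` in [0, 1) biases steps back toward the centroid so chains can
    be generated at roughly globular extent.  ``min_sep`` keeps non-bonded
    beads from starting inside each other's repulsive core.
    """
    pos = np.zeros((n, 3))
    if min_sep is None:
        min_sep = 0.8 * r0
    min_sep = min(min_sep, 1.9 * r0)  # geometric feasibility for 1-3 contacts
    for i in range(1, n):
        for _ in range(200):
            step = rng.normal(size=3)
            if compact > 0 and i > 1:
                centroid = pos[:i].mean(axis=0)
                pull = centroid - pos[i - 1]
                norm = np.linalg.norm(pull)
                if norm > 0:
                    step = (1 - compact) * step + compact * pull / norm
            step /= np.linalg.norm(step)
            cand = pos[i - 1] + r0 * step
            if i < 2 or np.min(np.linalg.norm(pos[: i - 1] - cand, axis=1)) > min_sep:
                pos[i] = cand
                break
        else:  # pragma: no cover - extremely unlikely
            pos[i] = cand
    return pos


def build_single_chain(
    sequence: str,
    ff: ForceFieldParameters,
    box_margin: float = 50.0,
    seed: int = 0,
) -> ParticleSystem:
    """One chain in a box large enough to avoid self-interaction via images."""
    if not sequence:
        raise SequenceError("empty sequence")
    ff.validate(sequence)
    rng = np.random.default_rng(seed)
    r0 = ff.bond.r0
    pos = _random_walk(
        len(sequence), r0, rng, min_sep=0.9 * _max_sigma(ff, sequence)
    )
    edge = (len(sequence) - 1) * r0 + 2.0 * box_margin
    box = np.array([edge, edge, edge])
    pos = pos - pos.mean(axis=0) + box / 2.0
    chain = ChainTopology(sequence, first_index=0, bond_r0=r0, bond_k=ff.bond.k)
    system = ParticleSystem(
        positions=pos,
        velocities=np.zeros_like(pos),
        chains=[chain],
        box=box,
    )
    system.wrap()
    return system


def build_slab(
    sequences: list[str],
    ff: ForceFieldParameters,
    target_concentration: float,
    dense_density: float = 0.9,
    n_replicates: int | None = None,
    seed: int = 0,
    relax: "object | None" = None,
) -> ParticleSystem:
    """Construct a dense slab extended along z to a target bulk concentration.

    Chains are replicated on a cubic lattice (replicate rule based on length),
    the box is deterministically rescaled to the requested dense density
    (optionally interleaved with relaxation via ``relax(system) -> system``),
    then the z-dimension is extended so total mass / volume equals
    ``target_concentration`` (g/L).
    """
    if target_concentration <= 0:
        raise GeometryError("target_concentration must be positive")
    if dense_density <= 0:
        raise GeometryError("dense_density must be positive")
    if len(sequences) != 1:
        raise SequenceError("slab builder expects a single sequence species")
    sequence = sequences[0]
    ff.validate(sequence)
    if n_replicates is None:
        n_replicates = replicate_count(len(sequence))
    side = round(n_replicates ** (1.0 / 3.0))
    if side**3 != n_replicates:
        raise GeometryError(f"replicate count {n_replicates} is not a cube")

    rng = np.random.default_rng(seed)
    r0 = ff.bond.r0
    template = _random_walk(
        len(sequence), r0, rng, compact=0.3,
        min_sep=0.9 * _max_sigma(ff, sequence),
    )
    template -= template.mean(axis=0)
    extent = 2.0 * np.abs(template).max() + 4.0

    chains: list[ChainTopology] = []
    blocks = []
    for ix in range(side):
        for iy in range(side):
            for iz in range(side):
                offset = (np.array([ix, iy, iz]) + 0.5) * extent
                blocks.append(template + offset)
                chains.append(
                    ChainTopology(
                        sequence,
                        first_index=len(chains) * len(sequence),
                        bond_r0=r0,
                        bond_k=ff.bond.k,
                    )
                )
    pos = np.vstack(blocks)
    box = np.array([side * extent] * 3)
    system = ParticleSystem(
        positions=pos, velocities=np.zeros_like(pos), chains=chains, box=box
    )
    system.wrap()

    # Staged affine compression to the dense target (deterministic barostat
    # substitute); relaxation between stages is caller-supplied.
    mass_g = system.total_mass(ff) / AVOGADRO
    target_volume = mass_g / dense_density * 1e24  # A^3
    target_edge = target_volume ** (1.0 / 3.0)
    n_stages = 8
    for stage in range(n_stages):
        frac = (stage + 1) / n_stages
        new_edge = box[0] * (target_edge / box[0]) ** (1.0 / (n_stages - stage))
        scale = new_edge / system.box[0]
        system.positions *= scale
        system.box = system.box * scale
        system.wrap()
        if relax is not None and frac < 1.0:
            system = relax(system)
    # exact final density
    scale = target_edge / system.box[0]
    system.positions *= scale
    system.box = system.box * scale
    system.wrap()
    if relax is not None:
        system = relax(system)

    # z-extension to the requested bulk concentration (g/L = 1e-3 g/cm^3)
    conc_gcc = target_concentration * 1e-3
    lx, ly = system.box[0], system.box[1]
    lz = mass_g * 1e24 / (conc_gcc * lx * ly)
    if lz < system.box[2]:
        raise GeometryError(
            "target concentration exceeds the dense-slab density; "
            "extended box would be shorter than the slab"
        )
    shift = (lz - system.box[2]) / 2.0
    system.positions[:, 2] += shift
    system.box = np.array([lx, ly, lz])
    system.wrap()
    return system


# ------------------------------------------------------------------ output

def write_xyz(path: str | Path, system: ParticleSystem, comment: str = "") -> None:
    with open(path, "w") as fh:
        fh.write(f"{system.n_beads}\n{comment}\n")
        for code, p in zip(system.residue_codes, system.positions):
            fh.write(f"{code} {p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")


def write_lammps_data(path: str | Path, system: ParticleSystem, ff: ForceFieldParameters) -> None:
    """LAMMPS data file (atom_style full) in real units."""
    codes = sorted(set(system.residue_codes))
    type_of = {c: k + 1 for k, c in enumerate(codes)}
    bonds = system.bonds()
    mol = system.molecule_ids()
    lines = [
        "coarse-grained bead-chain system (real units)",
        "",
        f"{system.n_beads} atoms",
        f"{len(bonds)} bonds",
        f"{len(codes)} atom types",
        "1 bond types",
        "",
        f"0.0 {system.box[0]:.8f} xlo xhi",
        f"0.0 {system.box[1]:.8f} ylo yhi",
        f"0.0 {system.box[2]:.8f} zlo zhi",
        "",
        "Masses",
        "",
    ]
    for c in codes:
        lines.append(f"{type_of[c]} {ff.residue(c).mass:.4f}  # {c}")
    lines += ["", "Atoms  # full", ""]
    for i, (code, p) in enumerate(zip(system.residue_codes, system.positions)):
        q = ff.residue(code).charge
        lines.append(
            f"{i + 1} {mol[i] + 1} {type_of[code]} {q:.4f} "
            f"{p[0]:.8f} {p[1]:.8f} {p[2]:.8f}"
        )
    lines += ["", "Bonds", ""]
    for k, (a, b) in enumerate(bonds):
        lines.append(f"{k + 1} 1 {a + 1} {b + 1}")
    Path(path).write_text("\n".join(lines) + "\n")
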