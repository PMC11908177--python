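# cgtherm

Temperature-dependent residue-level coarse-grained modelling of protein
LCST/UCST phase behaviour.

The package implements a one-bead-per-residue implicit-solvent force field in
which short-range nonbonded interactions follow the Wang–Frenkel potential
with well depths that, for residue pairs containing a hydrophobic residue
(A, V, I, L, M), are rescaled as an explicit parabolic function of
temperature relative to 298.15 K. Negative scaled well depths switch the pair
to a purely repulsive WCA-style truncation that preserves bead size.
Electrostatics are Yukawa with a temperature-dependent dielectric constant
(`ε(T) = 1 + ρ_water(T)·d(T)`, Kell density polynomial, linear `d(T)` fitted
to an experimental water-dielectric table) and matching inverse Debye length.

On top of the force field it provides:

- **system building** — FASTA input, the 64/27 replicate rule, dense-slab
  construction with deterministic compression and z-extension to a target
  concentration, single-chain boxes for scaling runs;
- **a desk-scale MD engine** — BAOAB Langevin dynamics (velocity Verlet at
  zero friction), 10 fs timestep and 5 ps thermostat relaxation by default,
  numba-compiled cell-list/all-pairs force kernels, steepest-descent
  minimisation, LAMMPS-style dump / XYZ / data-file output;
- **analysis** — z-density profiles, finite-size cloud-point detection
  (sharp-spike criterion with persistence), coexistence densities from slab
  profiles, critical-point fitting via the laws of coexistence densities and
  rectilinear diameters, radius-of-gyration series, the finite-chain
  scaling-exponent solver (b = 5.5 Å, γ = 1.1615) and ν = 0.5 coil–globule
  interpolation, 3-block error analysis, and the absorbance-0.301 cloud-point
  convention;
- **fixtures** — seeded synthetic parameter sets (complete 20-residue
  schema), planted-truth density profiles, binodals, Rg series and absorbance
  curves, so every pipeline stage is testable fully offline;
- **LAMMPS export** — `pair_style table` files per temperature plus a data
  file and input-script template for production-scale runs.

Units follow the LAMMPS `real` convention (kcal/mol, Å, fs, amu, e, K);
model validity is the liquid-water window 273–373 K.

## CLI

```bash
# pair tables + input template for LAMMPS, one table per temperature
cgtherm tables --ff ff/forcefield.json --temps 280,300,320 --out out/tables

# finite-size cloud-point pipeline (desk-scale override shown)
cgtherm cloudpoint --fasta seq.fasta --ff ff/forcefield.json \
    --concentration 30 --grid 330,340,350 --n-replicates 8 \
    --production 1.0 --out out/cp

# single-chain ladder: Rg, nu(T), coil-globule temperature
cgtherm flory --fasta seq.fasta --ff ff/forcefield.json \
    --grid 280,300,320,340,360 --out out/flory

# binodal + critical point from coexistence data (CSV or dump directory)
cgtherm binodal --coex coexistence.csv --out out/fit

# one trajectory with dump/XYZ/data output
cgtherm simulate --fasta seq.fasta --temperature 300 --mode chain --out out/sim
```

Force-field parameters live in three CSV tables (residues, pairs, scaling
coefficients) referenced by a JSON/YAML manifest; `ForceFieldParameters.save`
/ `.load` round-trip them losslessly, and `cgtherm.fixtures.make_param_set`
writes complete synthetic sets in the same schema. Every command records a
`manifest.json` (config, seed, version, input hashes) for reproducibility.

## Layout

```
src/cgtherm/
  constants.py        physical constants, unit conversions, water tables
  forcefield/         parameters + I/O, electrostatics, pair potentials,
                      LAMMPS table export
  system_builder.py   FASTA, replicate rule, slab/single-chain construction
  md_engine.py        Langevin engine, minimiser, trajectory I/O
  _kernels.py         numba force/integrator kernels
  analysis.py         profiles, cloud point, binodal, Rg/nu, block errors
  fixtures.py         synthetic ground-truth generators
  cli.py              command-line entry points
```
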