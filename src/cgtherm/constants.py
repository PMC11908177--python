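"""Physical constants and unit conversions.

Unit system follows the LAMMPS ``real`` convention: energies in kcal/mol,
distances in angstrom, time in femtoseconds, masses in amu, charges in
elementary charges, temperature in kelvin.
"""

from __future__ import annotations

import numpy as np

# CODATA 2018
ELEMENTARY_CHARGE = 1.602176634e-19  # C
VACUUM_PERMITTIVITY = 8.8541878128e-12  # C^2 N^-1 m^-2
BOLTZMANN_SI = 1.380649e-23  # J/K
AVOGADRO = 6.02214076e23  # 1/mol

#: Boltzmann constant, kcal/(mol K)
KB = BOLTZMANN_SI * AVOGADRO / 4184.0

#: e^2/(4 pi eps0) in kcal*angstrom/mol, i.e. the Coulomb prefactor such that
#: U = COULOMB * q_i q_j / (eps_r * r) with q in e and r in angstrom.
COULOMB = (
    ELEMENTARY_CHARGE**2
    / (4.0 * np.pi * VACUUM_PERMITTIVITY)
    * AVOGADRO
    / 4184.0
    * 1e10
)

#: kcal/mol per (amu angstrom^2 / fs^2): kinetic-energy conversion.
MVV2E = 1.66053906660e-27 * 1e10 * AVOGADRO / 4184.0  # = m_u * A^2/fs^2 in kcal/mol
#: angstrom/fs^2 per (kcal/mol/angstrom/amu): force-to-acceleration conversion.
FTM2V = 1.0 / MVV2E

#: Model validity window: liquid water at ambient pressure.
T_MIN = 273.0
T_MAX = 373.0

#: Default reference temperature for well-depth scaling, K.
T_REF = 298.15

# Kell (1975) polynomial for the density of air-free water at 1 atm,
# J. Chem. Eng. Data 20, 97. Input celsius, output kg/m^3.
KELL_NUMERATOR = np.array(
    [999.83952, 16.945176, -7.9870401e-3, -46.170461e-6, 105.56302e-9, -280.54253e-12]
)
KELL_DENOMINATOR_B = 16.879850e-3

# Static dielectric constant of liquid water, experimental smoothing of
# Malmberg & Maryott, J. Res. NBS 56, 1 (1956); columns (T kelvin, eps).
WATER_DIELECTRIC_TABLE = np.array(
    [
        [273.15, 87.740],
        [278.15, 85.763],
        [283.15, 83.832],
        [288.15, 81.945],
        [293.15, 80.103],
        [298.15, 78.304],
        [303.15, 76.546],
        [308.15, 74.828],
        [313.15, 73.151],
        [318.15, 71.512],
        [323.15, 69.910],
        [328.15, 68.345],
        [333.15, 66.815],
        [338.15, 65.319],
        [343.15, 63.857],
        [348.15, 62.427],
        [353.15, 61.027],
        [358.15, 59.659],
        [363.15, 58.319],
        [368.15, 57.007],
        [373.15, 55.720],
    ]
)

#: Default coefficients of the linear solvent parameter d(T) = d0 + d1*T,
#: obtained by least squares of eps(T) = 1 + rho_water(T) * d(T) against
#: WATER_DIELECTRIC_TABLE (see forcefield.electrostatics.fit_d_coefficients).
DEFAULT_D_COEFFICIENTS = (165.44834245077436, -0.2937227721677854)

#: Twenty-residue alphabet, alphabetical one-letter codes.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Residues whose pair interactions acquire an explicit temperature scaling.
HYDROPHOBIC_RESIDUES = frozenset("AVILM")

#: Average residue masses, amu (standard amino-acid residue masses).
RESIDUE_MASSES = {
    "A": 71.0788, "C": 103.1388, "D": 115.0886, "E": 129.1155, "F": 147.1766,
    "G": 57.0519, "H": 137.1411, "I": 113.1594, "K": 128.1741, "L": 113.1594,
    "M": 131.1926, "N": 114.1038, "P": 97.1167, "Q": 128.1307, "R": 156.1875,
    "S": 87.0782, "T": 101.1051, "V": 99.1326, "W": 186.2132, "Y": 163.1760,
}

#: Integer charges at neutral pH used by the synthetic parameter sets.
RESIDUE_CHARGES = {aa: 0.0 for aa in AMINO_ACIDS}
RESIDUE_CHARGES.update({"D": -1.0, "E": -1.0, "K": 1.0, "R": 1.0})
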