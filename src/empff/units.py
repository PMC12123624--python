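"""Physical constants and unit conversions.

Internal units throughout the package: energy in eV, length in Å, time in fs,
mass in unified atomic mass units (amu), temperature in K.  Velocities are
Å/fs.  Stress is eV/Å³.
"""

import numpy as np

# Boltzmann constant, eV/K (CODATA)
KB_EV = 8.617333262e-5

# Molar gas constant in kcal/(mol K)
R_KCAL = 1.987204259e-3

# 1 eV per particle = 23.060548 kcal/mol
EV_TO_KCALMOL = 23.060548
KCALMOL_TO_EV = 1.0 / EV_TO_KCALMOL
# 1 kcal/mol = 43.3641 meV
KCALMOL_TO_MEV = 1000.0 * KCALMOL_TO_EV

# 1 amu (Å/fs)^2 in eV: m v^2 conversion for kinetic energy
AMU_A2_FS2_TO_EV = 1.0364269574711572e2

# acceleration: F[eV/Å] / m[amu] -> Å/fs² requires dividing by this factor
# (inverse of the kinetic-energy conversion)
FORCE_MASS_TO_ACC = 1.0 / AMU_A2_FS2_TO_EV

# 1 amu/Å³ in g/cm³
AMU_A3_TO_G_CM3 = 1.66053906660

# frequency 1/fs -> wavenumber cm⁻¹ (divide by c in cm/fs)
INV_FS_TO_CM1 = 1.0e15 / 2.99792458e10

# Atomic masses (amu) and covalent radii (Å) for the organic force-field
# element range this package targets (H through I).
ATOMIC_MASSES = {
    1: 1.008, 2: 4.0026, 3: 6.94, 4: 9.0122, 5: 10.81, 6: 12.011,
    7: 14.007, 8: 15.999, 9: 18.998, 10: 20.180, 11: 22.990, 12: 24.305,
    13: 26.982, 14: 28.085, 15: 30.974, 16: 32.06, 17: 35.45, 18: 39.948,
    19: 39.098, 20: 40.078, 35: 79.904, 53: 126.904,
}

COVALENT_RADII = {
    1: 0.31, 2: 0.28, 3: 1.28, 4: 0.96, 5: 0.84, 6: 0.76,
    7: 0.71, 8: 0.66, 9: 0.57, 10: 0.58, 11: 1.66, 12: 1.41,
    13: 1.21, 14: 1.11, 15: 1.07, 16: 1.05, 17: 1.02, 18: 1.06,
    19: 2.03, 20: 1.76, 35: 1.20, 53: 1.39,
}

CHEMICAL_SYMBOLS = {
    1: "H", 2: "He", 3: "Li", 4: "Be", 5: "B", 6: "C", 7: "N", 8: "O",
    9: "F", 10: "Ne", 11: "Na", 12: "Mg", 13: "Al", 14: "Si", 15: "P",
    16: "S", 17: "Cl", 18: "Ar", 19: "K", 20: "Ca", 35: "Br", 53: "I",
}
SYMBOL_TO_Z = {s: z for z, s in CHEMICAL_SYMBOLS.items()}


def masses_for(species) -> np.ndarray:
    """Atomic masses (amu) for an array of atomic numbers."""
    return np.array([ATOMIC_MASSES[int(z)] for z in species], dtype=float)
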