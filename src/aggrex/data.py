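"""Element property tables and physical constants.

Covalent radii follow Cordero et al. (single-bond values); van der Waals
radii follow Bondi with Alvarez extensions for the heavier elements.
All radii in Angstrom.
"""

from __future__ import annotations

# 1 Bohr in Angstrom (CODATA)
BOHR_IN_ANGSTROM = 0.529177210903
ANGSTROM_IN_BOHR = 1.0 / BOHR_IN_ANGSTROM
HARTREE_IN_EV = 27.211386245988

COVALENT_RADII: dict[str, float] = {
    "H": 0.31, "He": 0.28,
    "Li": 1.28, "Be": 0.96, "B": 0.84, "C": 0.76, "N": 0.71, "O": 0.66,
    "F": 0.57, "Ne": 0.58,
    "Na": 1.66, "Mg": 1.41, "Al": 1.21, "Si": 1.11, "P": 1.07, "S": 1.05,
    "Cl": 1.02, "Ar": 1.06,
    "K": 2.03, "Ca": 1.76, "Ti": 1.60, "Cr": 1.39, "Mn": 1.39, "Fe": 1.32,
    "Co": 1.26, "Ni": 1.24, "Cu": 1.32, "Zn": 1.22, "Br": 1.20, "Kr": 1.16,
    "Rb": 2.20, "Sr": 1.95, "Ag": 1.45, "I": 1.39, "Xe": 1.40,
    "Cs": 2.44, "Ba": 2.15,
}

VDW_RADII: dict[str, float] = {
    "H": 1.20, "He": 1.40,
    "Li": 1.82, "Be": 1.53, "B": 1.92, "C": 1.70, "N": 1.55, "O": 1.52,
    "F": 1.47, "Ne": 1.54,
    "Na": 2.27, "Mg": 1.73, "Al": 1.84, "Si": 2.10, "P": 1.80, "S": 1.80,
    "Cl": 1.75, "Ar": 1.88,
    "K": 2.75, "Ca": 2.31, "Ti": 2.15, "Cr": 2.06, "Mn": 2.05, "Fe": 2.04,
    "Co": 2.00, "Ni": 1.97, "Cu": 1.96, "Zn": 2.01, "Br": 1.85, "Kr": 2.02,
    "Rb": 3.03, "Sr": 2.49, "Ag": 2.03, "I": 1.98, "Xe": 2.16,
    "Cs": 3.43, "Ba": 2.68,
}

ATOMIC_NUMBERS: dict[str, int] = {
    "H": 1, "He": 2, "Li": 3, "Be": 4, "B": 5, "C": 6, "N": 7, "O": 8,
    "F": 9, "Ne": 10, "Na": 11, "Mg": 12, "Al": 13, "Si": 14, "P": 15,
    "S": 16, "Cl": 17, "Ar": 18, "K": 19, "Ca": 20, "Ti": 22, "Cr": 24,
    "Mn": 25, "Fe": 26, "Co": 27, "Ni": 28, "Cu": 29, "Zn": 30, "Br": 35,
    "Kr": 36, "Rb": 37, "Sr": 38, "Ag": 47, "I": 53, "Xe": 54, "Cs": 55,
    "Ba": 56,
}

SYMBOL_OF_NUMBER: dict[int, str] = {z: sym for sym, z in ATOMIC_NUMBERS.items()}
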