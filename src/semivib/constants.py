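"""Physical constants and unit conversions (CODATA 2018).

Everything inside the package is in Hartree atomic units: energies in
Hartree, lengths in Bohr, masses in electron masses, time in ħ/Eh.
Conversions to the spectroscopist's units (cm⁻¹, Å, amu) happen only at
I/O boundaries.
"""

from __future__ import annotations

# 1 Hartree in wavenumbers
HARTREE_TO_CM = 219474.6313632

# 1 Bohr in Ångström
BOHR_TO_ANGSTROM = 0.529177210903
ANGSTROM_TO_BOHR = 1.0 / BOHR_TO_ANGSTROM

# 1 unified atomic mass unit in electron masses
AMU_TO_ME = 1822.888486209

# Standard atomic weights (amu) for the elements this package needs.
ATOMIC_MASSES = {
    "H": 1.00782503207,
    "D": 2.01410177785,
    "He": 4.002602,
    "Li": 6.94,
    "B": 10.81,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "F": 18.99840322,
    "Ne": 20.1797,
    "Na": 22.98976928,
    "Mg": 24.305,
    "P": 30.97376163,
    "S": 31.97207100,
    "Cl": 34.96885268,
    "Ar": 39.948,
    "K": 39.0983,
    "Ca": 40.078,
    "Br": 78.9183371,
    "I": 126.904473,
}

ATOMIC_NUMBERS = {
    "H": 1, "D": 1, "He": 2, "Li": 3, "B": 5, "C": 6, "N": 7, "O": 8,
    "F": 9, "Ne": 10, "Na": 11, "Mg": 12, "P": 15, "S": 16, "Cl": 17,
    "Ar": 18, "K": 19, "Ca": 20, "Br": 35, "I": 53,
}
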