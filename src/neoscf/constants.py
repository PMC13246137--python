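"""Physical constants and unit conversions.

Internal units are atomic units (bohr, Hartree) everywhere; external geometry
files use Angstrom.  The single conversion constant lives here.
"""

# Angstrom per bohr (CODATA value used for all XYZ <-> internal conversions).
BOHR_RADIUS_ANGSTROM = 0.52917721092

#: Proton mass in units of the electron mass.
PROTON_MASS_AU = 1836.15267343

#: Nuclear charges of the elements the built-in bases cover.
ELEMENT_CHARGES = {
    "H": 1, "He": 2,
    "Li": 3, "Be": 4, "B": 5, "C": 6, "N": 7, "O": 8, "F": 9, "Ne": 10,
    "Na": 11, "Mg": 12, "Al": 13, "Si": 14, "P": 15, "S": 16, "Cl": 17,
    "Ar": 18,
}


def angstrom_to_bohr(x):
    return x / BOHR_RADIUS_ANGSTROM


def bohr_to_angstrom(x):
    return x * BOHR_RADIUS_ANGSTROM
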