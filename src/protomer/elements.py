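"""Static per-element data tables.

The tables are snapshotted in the repository so descriptor values never
drift with dependency versions.  Sources: IUPAC 2021 standard atomic
weights, Pauling electronegativities, Cordero (2008) covalent radii,
Bondi (1964) van der Waals radii, and recommended static dipole
polarizabilities (Schwerdtfeger & Nagle 2019 compilation, converted to
cubic angstroms).  Coverage is the organic/bio-organic element set the
pipeline supports; asking for anything else raises
:class:`~protomer.errors.ConfigurationError` naming the element.
"""

from __future__ import annotations

from .errors import ConfigurationError

# g/mol
ATOMIC_MASS: dict[str, float] = {
    "H": 1.008,
    "B": 10.81,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998403163,
    "Si": 28.085,
    "P": 30.973761998,
    "S": 32.06,
    "Cl": 35.45,
    "Se": 78.971,
    "Br": 79.904,
    "I": 126.90447,
}

# Pauling scale (dimensionless)
ELECTRONEGATIVITY: dict[str, float] = {
    "H": 2.20,
    "B": 2.04,
    "C": 2.55,
    "N": 3.04,
    "O": 3.44,
    "F": 3.98,
    "Si": 1.90,
    "P": 2.19,
    "S": 2.58,
    "Cl": 3.16,
    "Se": 2.55,
    "Br": 2.96,
    "I": 2.66,
}

# Cordero single-bond covalent radii, angstrom (C is the sp3 value)
COVALENT_RADIUS: dict[str, float] = {
    "H": 0.31,
    "B": 0.84,
    "C": 0.76,
    "N": 0.71,
    "O": 0.66,
    "F": 0.57,
    "Si": 1.11,
    "P": 1.07,
    "S": 1.05,
    "Cl": 1.02,
    "Se": 1.20,
    "Br": 1.20,
    "I": 1.39,
}

# Bondi van der Waals radii, angstrom
VDW_RADIUS: dict[str, float] = {
    "H": 1.20,
    "B": 1.92,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "Si": 2.10,
    "P": 1.80,
    "S": 1.80,
    "Cl": 1.75,
    "Se": 1.90,
    "Br": 1.85,
    "I": 1.98,
}

# Static dipole polarizability, cubic angstrom
POLARIZABILITY: dict[str, float] = {
    "H": 0.667,
    "B": 3.04,
    "C": 1.76,
    "N": 1.10,
    "O": 0.802,
    "F": 0.557,
    "Si": 5.53,
    "P": 3.63,
    "S": 2.90,
    "Cl": 2.18,
    "Se": 3.77,
    "Br": 3.05,
    "I": 5.35,
}

HALOGENS = frozenset({"F", "Cl", "Br", "I"})
OTHERGENS = frozenset({"S", "P", "Se"})  # "othergen" descriptor group


def _lookup(table: dict[str, float], element: str, what: str) -> float:
    try:
        return table[element]
    except KeyError:
        raise ConfigurationError(
            f"element '{element}' has no tabulated {what}"
        ) from None


def atomic_mass(element: str) -> float:
    return _lookup(ATOMIC_MASS, element, "atomic mass")


def electronegativity(element: str) -> float:
    return _lookup(ELECTRONEGATIVITY, element, "electronegativity")


def covalent_radius(element: str) -> float:
    return _lookup(COVALENT_RADIUS, element, "covalent radius")


def vdw_radius(element: str) -> float:
    return _lookup(VDW_RADIUS, element, "van der Waals radius")


def polarizability(element: str) -> float:
    return _lookup(POLARIZABILITY, element, "static dipole polarizability")
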