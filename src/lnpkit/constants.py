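"""Physical constants and small element/molecule lookup tables.

Unit conventions used throughout the package:

* distances at public interfaces: nm (molecular) or nm (diameters); q in 1/Angstrom
* SAXS internals: lengths in Angstrom, absolute intensity in 1/Angstrom
  (the common reduced-data unit 1/mm is converted at ingest, 1 mm^-1 = 1e-7 A^-1)
* scattering length densities quoted in units of 1e-6 A^-2
* energies: J/mol; temperature: K
"""

from __future__ import annotations

import re

#: molar gas constant, J/(mol K)
R_GAS = 8.314462618

#: Avogadro constant, 1/mol
N_AVOGADRO = 6.02214076e23

#: classical electron radius, cm
R_ELECTRON_CM = 2.8179403262e-13

#: conversion of absolute SAXS intensity, 1/mm -> 1/Angstrom
MM_INV_TO_A_INV = 1.0e-7

#: Hansen total solubility parameter of softwood Kraft lignin, MPa^0.5
DELTA_SKL = 27.4

#: Hansen total solubility parameter of water, MPa^0.5
DELTA_WATER = 47.8

#: molar volume of water, cm^3/mol (reference volume for solvent-water chi)
V_WATER = 18.07

#: default temperature for solution thermodynamics, K
T_DEFAULT = 298.15

#: assumed mass density of lignin nanoparticles, g/cm^3
LNP_DENSITY = 1.4

#: X-ray SLD of water at Cu K-alpha, in 1e-6 A^-2
SLD_WATER_1E6 = 9.469

# Element data: atomic number Z, standard atomic weight A (g/mol), and the
# real anomalous dispersion correction f' at Cu K-alpha (8.05 keV, Henke
# tables).  f' matters at the 0.5% level for O and S and is applied by
# default in SLD calculations.
ELEMENTS: dict[str, tuple[int, float, float]] = {
    "H": (1, 1.008, 0.0),
    "C": (6, 12.011, 0.0181),
    "N": (7, 14.007, 0.0311),
    "O": (8, 15.999, 0.0492),
    "F": (9, 18.998, 0.0727),
    "Na": (11, 22.990, 0.1353),
    "P": (15, 30.974, 0.2955),
    "S": (16, 32.06, 0.3331),
    "Cl": (17, 35.45, 0.3639),
}

#: Bondi van der Waals radii, nm (overridable in SASA calls)
BONDI_RADII_NM: dict[str, float] = {
    "H": 0.120,
    "C": 0.170,
    "N": 0.155,
    "O": 0.152,
    "F": 0.147,
    "P": 0.180,
    "S": 0.180,
    "Cl": 0.175,
}

#: empirical formulas of the solvent molecules handled by the generator
MOLECULE_FORMULAS: dict[str, str] = {
    "water": "H2O",
    "acetone": "C3H6O",
    "thf": "C4H8O",
    "dxn": "C4H8O2",
    "dmso": "C2H6OS",
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def molar_mass(formula: str) -> float:
    """Molar mass in g/mol of an empirical formula such as ``C68H74O22``.

    Raises ``ValueError`` for unknown element symbols.
    """
    mass = 0.0
    consumed = 0
    for sym, count in _FORMULA_TOKEN.findall(formula):
        if not sym:
            continue
        if sym not in ELEMENTS:
            raise ValueError(f"unknown element symbol {sym!r} in formula {formula!r}")
        mass += ELEMENTS[sym][1] * (int(count) if count else 1)
        consumed += len(sym) + len(count)
    if consumed != len(formula):
        raise ValueError(f"could not parse formula {formula!r}")
    return mass


def molecule_molar_mass(molecule_type: str) -> float:
    """Molar mass of a named molecule type (``water``, ``acetone``, ...)."""
    key = molecule_type.lower()
    if key not in MOLECULE_FORMULAS:
        raise ValueError(f"unknown molecule type {molecule_type!r}")
    return molar_mass(MOLECULE_FORMULAS[key])
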