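"""Flory-Huggins solvent screening for lignin nanoprecipitation.

Nanoprecipitation forms lignin nanoparticles (LNPs) by diluting a lignin
solution in a water-miscible organic solvent with water.  Two solution
descriptors rationalise the resulting particle sizes:

* the Flory-Huggins interaction parameter
  ``chi = V * (delta_1 - delta_2)**2 / (R * T)``
  built from Hansen total solubility parameters (MPa^0.5) and a reference
  molar volume V (cm^3/mol) -- lower chi means stronger solvent-solute
  affinity; and
* the supersaturation level ``S = s75 / s21``, the ratio of lignin
  solubility degrees before (75 wt% organic) and after (21 wt% organic)
  the anti-solvent dilution -- higher S drives faster nucleation and
  smaller particles.

For solvent-solute pairs the reference volume is the organic solvent's
molar volume.  For solvent-water pairs this package uses the molar volume
of water (18.07 cm^3/mol); see docs/methods.md for the rationale behind
that convention.

Note MPa * cm^3 = J exactly, so chi is dimensionless without any further
conversion factor when V is in cm^3/mol and delta in MPa^0.5.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .constants import DELTA_SKL, DELTA_WATER, R_GAS, T_DEFAULT, V_WATER
from .errors import InvalidInputError

__all__ = [
    "SolventRecord",
    "ChiResult",
    "flory_huggins_chi",
    "supersaturation",
    "rank_solvents",
    "load_solvent_table",
    "format_chi",
]


@dataclass(frozen=True)
class SolventRecord:
    """One solvent system of the screening table.

    Attributes
    ----------
    name : solvent name (e.g. ``acetone``)
    delta : Hansen total solubility parameter of the organic solvent, MPa^0.5
    molar_volume : molar volume of the organic solvent, cm^3/mol
    s75 : solubility degree of 1 wt% lignin in the 75 wt% aqueous solvent
    s21 : solubility degree in the 21 wt% aqueous solvent
    """

    name: str
    delta: float
    molar_volume: float
    s75: float
    s21: float

    def __post_init__(self):
        if self.delta <= 0 or self.molar_volume <= 0:
            raise InvalidInputError(
                f"solvent {self.name!r}: delta and molar_volume must be positive"
            )
        if self.s75 < 0 or self.s21 < 0:
            raise InvalidInputError(f"solvent {self.name!r}: solubility degrees must be >= 0")


@dataclass(frozen=True)
class ChiResult:
    """A Flory-Huggins interaction parameter with the inputs that fix its scale."""

    chi: float
    reference_volume: float  # cm^3/mol
    temperature: float  # K


def flory_huggins_chi(
    reference_volume: float,
    delta_a: float,
    delta_b: float,
    temperature: float = T_DEFAULT,
) -> ChiResult:
    """Flory-Huggins chi from Hansen solubility parameters.

    chi = V (delta_a - delta_b)^2 / (R T), dimensionless.

    Parameters
    ----------
    reference_volume : reference molar volume, cm^3/mol
    delta_a, delta_b : Hansen total solubility parameters, MPa^0.5
    temperature : K
    """
    if reference_volume <= 0:
        raise InvalidInputError("reference_volume must be positive")
    if temperature <= 0:
        raise InvalidInputError("temperature must be positive")
    if delta_a <= 0 or delta_b <= 0:
        raise InvalidInputError("solubility parameters must be positive")
    chi = reference_volume * (delta_a - delta_b) ** 2 / (R_GAS * temperature)
    return ChiResult(chi=chi, reference_volume=reference_volume, temperature=temperature)


def supersaturation(s75: float, s21: float, name: str = "") -> float:
    """Supersaturation level S = s75/s21 of the anti-solvent dilution."""
    if s21 <= 0:
        label = f" for solvent {name!r}" if name else ""
        raise InvalidInputError(f"s21 must be positive{label} (got {s21})")
    return s75 / s21


def rank_solvents(
    records: list[SolventRecord],
    delta_solute: float = DELTA_SKL,
    temperature: float = T_DEFAULT,
    delta_water: float = DELTA_WATER,
    water_molar_volume: float = V_WATER,
) -> pd.DataFrame:
    """Screening report: chi_solvent-solute, chi_solvent-water and S per solvent.

    Returns a DataFrame sorted by unrounded chi_solvent_solute ascending
    (best solvent first), ties broken alphabetically by name.
    """
    if not records:
        raise InvalidInputError("rank_solvents requires at least one record")
    rows = []
    for rec in records:
        chi_ss = flory_huggins_chi(rec.molar_volume, rec.delta, delta_solute, temperature).chi
        chi_sw = flory_huggins_chi(water_molar_volume, rec.delta, delta_water, temperature).chi
        rows.append(
            {
                "name": rec.name,
                "chi_solvent_solute": chi_ss,
                "chi_solvent_water": chi_sw,
                "supersaturation": supersaturation(rec.s75, rec.s21, rec.name),
            }
        )
    table = pd.DataFrame(rows)
    table = table.sort_values(
        ["chi_solvent_solute", "name"], kind="mergesort", ignore_index=True
    )
    return table


def format_chi(chi: float) -> str:
    """Report rounding: one decimal, two decimals below 0.1 (so 0.014 -> '0.01')."""
    return f"{chi:.2f}" if abs(chi) < 0.1 else f"{chi:.1f}"


def load_solvent_table(path: str | Path | None = None) -> list[SolventRecord]:
    """Load a solvent table CSV (columns name,delta_MPa05,V_cm3mol,s75,s21).

    With no argument, loads the packaged screening table for aqueous
    acetone/THF/DXN/DMSO.
    """
    if path is None:
        ref = importlib.resources.files("lnpkit.data") / "solvents.csv"
        with importlib.resources.as_file(ref) as p:
            frame = pd.read_csv(p)
    else:
        frame = pd.read_csv(path)
    required = {"name", "delta_MPa05", "V_cm3mol", "s75", "s21"}
    missing = required - set(frame.columns)
    if missing:
        raise InvalidInputError(f"solvent table missing columns: {sorted(missing)}")
    return [
        SolventRecord(
            name=str(r["name"]),
            delta=float(r["delta_MPa05"]),
            molar_volume=float(r["V_cm3mol"]),
            s75=float(r["s75"]),
            s21=float(r["s21"]),
        )
        for _, r in frame.iterrows()
    ]
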