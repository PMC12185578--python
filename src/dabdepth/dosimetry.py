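"""Topical exposure dose arithmetic.

A fixed volume of biocide solution is pipetted into a cylindrical insert
sitting on the skin; the quantities of interest are the absolute mass
applied and the areal dose over the insert footprint.  For aqueous
solutions 1 ppm ≡ 1 mg/L, so concentration in g/L is ppm/1000.
"""

from __future__ import annotations

from dataclasses import dataclass

import math

import pandas as pd


@dataclass
class ExposureSpec:
    """One exposure condition: solution concentration, volume and insert."""

    name: str
    concentration_ppm: float
    volume_uL: float = 20.0
    insert_diameter_mm: float = 8.0
    molar_mass_g_per_mol: float | None = None

    def __post_init__(self) -> None:
        if self.concentration_ppm <= 0 or self.volume_uL <= 0 or self.insert_diameter_mm <= 0:
            raise ValueError("concentration, volume and diameter must be positive")

    @property
    def concentration_g_per_L(self) -> float:
        return self.concentration_ppm / 1000.0

    @property
    def concentration_percent(self) -> float:
        return self.concentration_ppm / 10_000.0


def applied_mass_ug(volume_uL: float, conc_g_per_L: float) -> float:
    """Mass delivered in µg (µL × g/L = µg)."""
    if volume_uL <= 0 or conc_g_per_L <= 0:
        raise ValueError("volume and concentration must be positive")
    return volume_uL * conc_g_per_L


def areal_dose_g_per_m2(mass_ug: float, diameter_mm: float) -> float:
    """Areal dose over the insert footprint, in g/m²."""
    if mass_ug <= 0 or diameter_mm <= 0:
        raise ValueError("mass and diameter must be positive")
    radius_m = diameter_mm * 1e-3 / 2.0
    return mass_ug * 1e-6 / (math.pi * radius_m**2)


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (display convention)."""
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


def exposure_table(specs: list[ExposureSpec]) -> pd.DataFrame:
    """Dose table for a set of exposure conditions.

    Full-precision columns plus 2-significant-figure display values.
    """
    rows = []
    for s in specs:
        mass = applied_mass_ug(s.volume_uL, s.concentration_g_per_L)
        dose = areal_dose_g_per_m2(mass, s.insert_diameter_mm)
        rows.append({
            "name": s.name,
            "molar_mass_g_per_mol": s.molar_mass_g_per_mol,
            "concentration_ppm": s.concentration_ppm,
            "concentration_g_per_L": s.concentration_g_per_L,
            "concentration_percent": s.concentration_percent,
            "mass_applied_ug": mass,
            "areal_dose_g_per_m2": dose,
            "areal_dose_display": round_sig(dose, 2),
        })
    return pd.DataFrame(rows)


#: the study's exposure conditions (20 µL in an 8 mm insert)
STUDY_EXPOSURES = [
    ExposureSpec("MCI", 30, molar_mass_g_per_mol=149.60),
    ExposureSpec("MI", 30, molar_mass_g_per_mol=115.15),
    ExposureSpec("MI", 300, molar_mass_g_per_mol=115.15),
    ExposureSpec("BIT", 300, molar_mass_g_per_mol=151.19),
    ExposureSpec("BIT", 500, molar_mass_g_per_mol=151.19),
    ExposureSpec("OIT", 300, molar_mass_g_per_mol=213.34),
    ExposureSpec("OIT", 600, molar_mass_g_per_mol=213.34),
]
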