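"""Closed-form physical-chemistry utilities.

Currently: Debye screening length of an electrolyte solution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["ElectrolyteConditions", "ionic_strength", "debye_length"]

# CODATA-rounded constants (SI)
VACUUM_PERMITTIVITY = 8.854e-12  # F/m
BOLTZMANN = 1.381e-23  # J/K
AVOGADRO = 6.022e23  # 1/mol
ELEMENTARY_CHARGE = 1.602e-19  # C


@dataclass(frozen=True)
class ElectrolyteConditions:
    """Solvent/electrolyte state needed for screening-length calculations.

    Attributes
    ----------
    relative_permittivity : float
        Dimensionless dielectric constant of the medium (~78.5 for water
        at 25 degC).
    temperature : float
        Absolute temperature in kelvin.
    ionic_strength : float
        Ionic strength in mol/L.
    """

    relative_permittivity: float
    temperature: float
    ionic_strength: float

    def __post_init__(self) -> None:
        if self.relative_permittivity <= 0:
            raise ValueError("relative_permittivity must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.ionic_strength <= 0:
            raise ValueError("ionic_strength must be positive")


def ionic_strength(ions: list[tuple[float, int]]) -> float:
    """Ionic strength I = 1/2 * sum(c_i * z_i**2) from (conc mol/L, charge) pairs."""
    if not ions:
        raise ValueError("ion list is empty")
    if any(c < 0 for c, _ in ions):
        raise ValueError("ion concentrations must be non-negative")
    return 0.5 * sum(c * z * z for c, z in ions)


def debye_length(cond: ElectrolyteConditions) -> float:
    """Debye screening length in nm.

    lambda_D = sqrt(eps_r * eps_0 * kB * T / (2 * NA * e^2 * I)), with the
    ionic strength converted from mol/L to mol/m^3 internally.
    """
    i_si = cond.ionic_strength * 1000.0  # mol/L -> mol/m^3
    lam_m = math.sqrt(
        cond.relative_permittivity
        * VACUUM_PERMITTIVITY
        * BOLTZMANN
        * cond.temperature
        / (2.0 * AVOGADRO * ELEMENTARY_CHARGE**2 * i_si)
    )
    return lam_m * 1e9
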