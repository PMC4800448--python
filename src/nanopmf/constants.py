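"""Physical constants and electrostatic length scales.

Internal unit conventions used throughout the package:

* lengths in angstrom (Å)
* energies in units of k_B T at the target temperature
* charges in units of the elementary charge e
* concentrations in mol/L unless noted otherwise
"""

from __future__ import annotations

import math

E_CHARGE = 1.602176634e-19  # C
EPS0 = 8.8541878128e-12  # F/m
KB = 1.380649e-23  # J/K
NA = 6.02214076e23  # 1/mol

#: conversion factor: mol/L -> number density in Å^-3
MOLAR_TO_PER_A3 = NA / 1.0e27

DEFAULT_TEMPERATURE = 298.15  # K (25 °C)
DEFAULT_DIELECTRIC = 78.0


def bjerrum_length(temperature: float = DEFAULT_TEMPERATURE,
                   dielectric: float = DEFAULT_DIELECTRIC) -> float:
    """Bjerrum length l_B = e^2 / (4 pi eps0 eps k_B T) in Å.

    The distance at which two unit charges in the dielectric continuum
    interact with energy k_B T; about 7.2 Å in water at 25 °C.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if dielectric <= 0:
        raise ValueError("dielectric constant must be positive")
    lb_m = E_CHARGE ** 2 / (4.0 * math.pi * EPS0 * dielectric * KB * temperature)
    return lb_m * 1.0e10


def debye_length_from_number_densities(densities_per_a3, valences,
                                       temperature: float = DEFAULT_TEMPERATURE,
                                       dielectric: float = DEFAULT_DIELECTRIC) -> float:
    """Debye screening length kappa^-1 in Å from species number densities (Å^-3).

    kappa^2 = 4 pi l_B sum_a n_a z_a^2.  Returns ``inf`` when the total ionic
    strength is zero (unscreened system); callers sizing simulation cells must
    then fall back to a geometric bound.
    """
    lb = bjerrum_length(temperature, dielectric)
    s = 0.0
    for n, z in zip(densities_per_a3, valences):
        if n < 0:
            raise ValueError("number densities must be non-negative")
        s += n * z * z
    if s == 0.0:
        return math.inf
    return 1.0 / math.sqrt(4.0 * math.pi * lb * s)
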