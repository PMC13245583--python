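"""Physical and physiological constants shared by the forward models and fitters.

Internal unit conventions (everywhere in the package):

* time in seconds, rates in s^-1
* magnetic field in tesla, susceptibility in ppm
* blood volume fractions, hematocrit, oxygen saturations as fractions in [0, 1]
* CBF in mL/100 g/min, CMRO2 in umol O2/100 g/min

Percent appears only at reporting boundaries (tables, TSV reports).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict


@dataclass(frozen=True)
class PhysicsConstants:
    """Fixed quantities entering the qBOLD, susceptibility, and Fick models.

    Attributes
    ----------
    gamma:
        Proton gyromagnetic ratio, rad/s/T.
    delta_chi_do:
        Susceptibility difference between fully deoxygenated and fully
        oxygenated erythrocytes, ppm per unit hematocrit, quoted in the
        cgs-style convention that carries an explicit 4*pi/3 sphere factor
        (see :attr:`dchi_do_eff`).
    chi_oxy:
        Susceptibility of fully oxygenated blood relative to water, ppm.
    c_rbc:
        Oxygen binding capacity of red blood cells, umol O2 / mL.
    sao2:
        Arterial oxygen saturation (fraction), assumed constant across
        healthy subjects.
    brain_density:
        Brain tissue density, g/mL.
    b0:
        Main magnetic field strength, tesla.
    chi_reference_offset:
        Additive offset (ppm) defining the susceptibility zero reference
        (0.0 = water). Exposed because the reference choice is a convention,
        not a measurement.
    """

    gamma: float = 2.67513e8
    delta_chi_do: float = 0.27
    chi_oxy: float = -0.03
    c_rbc: float = 19.93
    sao2: float = 0.98
    brain_density: float = 1.05
    b0: float = 3.0
    chi_reference_offset: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.sao2 <= 1.0:
            raise ValueError(f"sao2 must be in (0, 1], got {self.sao2}")
        for name in ("gamma", "delta_chi_do", "c_rbc", "brain_density", "b0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def dchi_do_eff(self) -> float:
        """Effective deoxy-blood susceptibility scale (ppm per unit Hct).

        The 4*pi/3 sphere prefactor is folded into the susceptibility scale
        once, here, so that the characteristic frequency and the voxel
        susceptibility model use the identical convention and remain an
        exactly self-consistent pair.
        """
        return (4.0 * math.pi / 3.0) * self.delta_chi_do

    @property
    def ca_per_hct(self) -> float:
        """Arterial O2 carrying capacity per unit hematocrit, umol O2/mL."""
        return self.c_rbc

    def to_dict(self) -> dict:
        return asdict(self)


DEFAULT_CONSTANTS = PhysicsConstants()
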