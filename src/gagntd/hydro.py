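"""Closed-form hydrodynamics: the Svedberg relation and frictional ratios.

Connects the measurable transport coefficients of a sedimenting species --
sedimentation coefficient ``s`` and diffusion coefficient ``D`` -- to its
molar mass ``M``, partial specific volume ``vbar`` and shape factor
``f/f0`` under stated solvent conditions.  These are the relations behind
every derived row of a standard AUC parameter table:

* Svedberg relation:        ``M = s R T / (D (1 - vbar rho))``
* friction from s:          ``f = M (1 - vbar rho) / (N_A s)``
* friction from D:          ``f = k_B T / D``
* anhydrous-sphere friction ``f0 = 6 pi eta r0``, ``r0 = (3 M vbar / (4 pi N_A))^(1/3)``

Units are CGS throughout (``s`` in seconds, ``D`` in cm^2/s, ``M`` in g/mol,
``vbar`` in ml/g, density in g/ml, viscosity in poise).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .constants import AVOGADRO, BOLTZMANN, GAS_CONSTANT


class NonSedimentingError(ValueError):
    """Raised when the buoyancy term (1 - vbar*rho) is not positive."""


@dataclass(frozen=True)
class SolutionConditions:
    """Solvent state: absolute temperature (K), density (g/ml), viscosity (poise)."""

    temperature: float
    density: float
    viscosity: float

    def __post_init__(self) -> None:
        if self.temperature <= 0 or self.density <= 0 or self.viscosity <= 0:
            raise ValueError("temperature, density and viscosity must be positive")


#: Pure water at 20 degC -- the reference state of s20,w / D20,w corrections.
WATER_20C = SolutionConditions(temperature=293.15, density=0.99823, viscosity=1.002e-2)

#: The dialysis buffer of the Gag-NtD experiments (20 mM Tris, 150 mM NaCl):
#: density as measured, 20 degC, water-like viscosity.
GAG_BUFFER = SolutionConditions(temperature=293.15, density=1.005, viscosity=1.002e-2)


@dataclass
class SpeciesHydro:
    """One sedimenting species.

    Parameters
    ----------
    molar_mass : float
        g/mol.
    vbar : float
        Partial specific volume, ml/g.
    s : float, optional
        Sedimentation coefficient in seconds (1 Svedberg = 1e-13 s).
    diffusion : float, optional
        Diffusion coefficient, cm^2/s.
    ff0 : float, optional
        Frictional ratio f/f0 (>= 1 for physical particles).
    extinction_280 : float, optional
        Molar extinction coefficient at 280 nm, 1/(M cm).
    loading_concentration : float, optional
        mol/L.
    """

    molar_mass: float
    vbar: float
    s: Optional[float] = None
    diffusion: Optional[float] = None
    ff0: Optional[float] = None
    extinction_280: Optional[float] = None
    loading_concentration: Optional[float] = None

    def __post_init__(self) -> None:
        if self.molar_mass <= 0:
            raise ValueError("molar_mass must be positive")
        if self.vbar <= 0:
            raise ValueError("vbar must be positive")
        if self.s is not None and self.s <= 0:
            raise ValueError("s must be positive when set")
        if self.diffusion is not None and self.diffusion <= 0:
            raise ValueError("diffusion must be positive when set")

    def with_transport(self, cond: SolutionConditions) -> "SpeciesHydro":
        """Return a copy with (s, D) filled in from (M, f/f0) via `sD_from_M`."""
        if self.ff0 is None:
            raise ValueError("f/f0 must be set to derive transport coefficients")
        s, d = sD_from_M(self.molar_mass, self.ff0, self.vbar, cond)
        return SpeciesHydro(
            molar_mass=self.molar_mass,
            vbar=self.vbar,
            s=s,
            diffusion=d,
            ff0=self.ff0,
            extinction_280=self.extinction_280,
            loading_concentration=self.loading_concentration,
        )


def buoyancy(vbar: float, cond: SolutionConditions) -> float:
    """The buoyancy factor (1 - vbar * rho); must be positive for sedimentation."""
    b = 1.0 - vbar * cond.density
    if b <= 0:
        raise NonSedimentingError(
            f"buoyancy term 1 - vbar*rho = {b:.4g} <= 0: species does not sediment"
        )
    return b


def svedberg_mass(s: float, diffusion: float, vbar: float, cond: SolutionConditions) -> float:
    """Molar mass from the Svedberg relation, M = s R T / (D (1 - vbar rho)).

    ``s`` in seconds, ``diffusion`` in cm^2/s; returns g/mol.
    """
    if s <= 0 or diffusion <= 0:
        raise ValueError("s and D must be positive")
    return s * GAS_CONSTANT * cond.temperature / (diffusion * buoyancy(vbar, cond))


def sphere_friction_f0(molar_mass: float, vbar: float, cond: SolutionConditions) -> float:
    """Stokes friction of the anhydrous sphere of equal mass and volume, g/s.

    No hydration shell is applied: f0 = 6 pi eta r0 with
    r0 = (3 M vbar / (4 pi N_A))^(1/3).
    """
    if molar_mass <= 0 or vbar <= 0:
        raise ValueError("molar_mass and vbar must be positive")
    r0 = (3.0 * molar_mass * vbar / (4.0 * np.pi * AVOGADRO)) ** (1.0 / 3.0)
    return 6.0 * np.pi * cond.viscosity * r0


def friction_from_s(s: float, molar_mass: float, vbar: float, cond: SolutionConditions) -> float:
    """Translational friction coefficient implied by s: f = M (1 - vbar rho)/(N_A s)."""
    if s <= 0:
        raise ValueError("s must be positive")
    return molar_mass * buoyancy(vbar, cond) / (AVOGADRO * s)


def friction_from_d(diffusion: float, cond: SolutionConditions) -> float:
    """Translational friction coefficient implied by D: f = k_B T / D."""
    if diffusion <= 0:
        raise ValueError("D must be positive")
    return BOLTZMANN * cond.temperature / diffusion


def frictional_ratio_from_s(
    s: float, molar_mass: float, vbar: float, cond: SolutionConditions
) -> float:
    """f/f0 computed from the sedimentation coefficient.

    A value below 1 is unphysical for a real particle and signals
    inconsistent inputs; it is returned as-is (callers may warn).
    """
    return friction_from_s(s, molar_mass, vbar, cond) / sphere_friction_f0(
        molar_mass, vbar, cond
    )


def frictional_ratio_from_d(
    diffusion: float, molar_mass: float, vbar: float, cond: SolutionConditions
) -> float:
    """f/f0 computed from the diffusion coefficient."""
    return friction_from_d(diffusion, cond) / sphere_friction_f0(molar_mass, vbar, cond)


def sD_from_M(
    molar_mass: float, ff0: float, vbar: float, cond: SolutionConditions
) -> tuple[float, float]:
    """Forward model: (s, D) of a species of mass M and shape factor f/f0.

    The returned pair satisfies the Svedberg relation exactly, so
    ``svedberg_mass(*sD_from_M(M, ...))`` round-trips to M.
    """
    if ff0 < 1.0:
        raise ValueError("f/f0 must be >= 1")
    f = ff0 * sphere_friction_f0(molar_mass, vbar, cond)
    s = molar_mass * buoyancy(vbar, cond) / (AVOGADRO * f)
    diffusion = BOLTZMANN * cond.temperature / f
    return s, diffusion


def mass_from_s_ff0(s: float, ff0: float, vbar: float, cond: SolutionConditions) -> float:
    """Invert s(M) at fixed f/f0: the mass whose sD_from_M gives this s.

    Since f0 scales as M^(1/3), s scales as M^(2/3) at fixed shape, giving
    the closed form M = (s N_A f0_coeff ff0 / (1 - vbar rho))^(3/2) with
    f0_coeff = 6 pi eta (3 vbar / (4 pi N_A))^(1/3).
    """
    if s <= 0:
        raise ValueError("s must be positive")
    f0_coeff = 6.0 * np.pi * cond.viscosity * (
        3.0 * vbar / (4.0 * np.pi * AVOGADRO)
    ) ** (1.0 / 3.0)
    return (s * AVOGADRO * f0_coeff * ff0 / buoyancy(vbar, cond)) ** 1.5


def d_from_s_ff0(s: float, ff0: float, vbar: float, cond: SolutionConditions) -> float:
    """Diffusion coefficient of the species with this s at fixed f/f0 and vbar."""
    m = mass_from_s_ff0(s, ff0, vbar, cond)
    return sD_from_M(m, ff0, vbar, cond)[1]
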