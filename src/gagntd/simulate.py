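"""Forward simulators for AUC and ITC experiments.

Produces every input the analysis pipeline consumes:

* sedimentation-velocity scan sets (Lamm-equation transport of one or more
  ideal species, absorbance or Rayleigh-interference optics),
* multi-speed sedimentation-equilibrium gradients (exponential closed form),
* equimolar protein + peptide binding mixtures in the fast-exchange limit,
* one-site ITC thermograms.

All randomness is Gaussian observation noise driven by an explicit seed, so
every simulation is bit-for-bit reproducible.  Default conditions mirror the
Gag-NtD study: 50,000 rpm velocity runs scanned every 180 s, 3 mm pathlength
cells for the 75 uM equimolar absorbance binding runs, equilibrium at
14-100 uM loading, and 20 x 2 ul injections of 1 mM peptide into 50 uM
protein in a 0.2026 ml calorimeter cell.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np

from .binding import complex_concentration
from .constants import rpm_to_rad_s
from .hydro import SolutionConditions, SpeciesHydro, sD_from_M
from .itc import wiseman_injection_heats
from .lamm import BINDING_GEOMETRY, CellGeometry, LammMesh, solve_lamm

Channel = Literal["absorbance280", "interference"]

#: community-standard refractive-index increment expressed as a fringe
#: coefficient, fringes * ml / (mg * cm)
FRINGE_COEFF = 3.3

#: default observation noise, signal units (the rmsd scale of typical fits)
DEFAULT_NOISE = 0.006


@dataclass
class SVScanSet:
    """A family of radial scans from one velocity run.

    ``signals`` has one row per scan time; radii are cell-centre positions
    of the simulation mesh (cm), strictly increasing within the cell.
    """

    omega: float
    scan_times: np.ndarray
    radii: np.ndarray
    signals: np.ndarray
    channel: Channel
    geometry: CellGeometry
    noise_sigma: float = 0.0

    def __post_init__(self) -> None:
        self.scan_times = np.asarray(self.scan_times, float)
        self.radii = np.asarray(self.radii, float)
        self.signals = np.asarray(self.signals, float)
        if self.signals.shape != (self.scan_times.size, self.radii.size):
            raise ValueError("signals must be (n_scans, n_radii)")
        if np.any(np.diff(self.radii) <= 0):
            raise ValueError("radius grid must be strictly increasing")
        g = self.geometry
        if self.radii[0] < g.meniscus - 1e-9 or self.radii[-1] > g.base + 1e-9:
            raise ValueError("radius grid must lie within [meniscus, base]")


@dataclass
class SEProfile:
    """One equilibrium gradient: rotor speed (rad/s), loading (mol/L), A(r)."""

    omega: float
    loading: float
    radii: np.ndarray
    signal: np.ndarray


@dataclass
class SEProfileSet:
    profiles: list[SEProfile]
    geometry: CellGeometry
    reference_radius: float

    def __len__(self) -> int:
        return len(self.profiles)


@dataclass
class ITCTitration:
    """An injection schedule plus per-injection heats (ucal)."""

    cell_volume: float  # ml
    cell_concentration: float  # mol/L, macromolecule in the cell
    syringe_concentration: float  # mol/L, titrant
    injection_volumes: np.ndarray  # ml per injection
    heats: np.ndarray  # ucal per injection

    def __post_init__(self) -> None:
        self.injection_volumes = np.asarray(self.injection_volumes, float)
        self.heats = np.asarray(self.heats, float)
        if self.cell_volume <= 0 or np.any(self.injection_volumes <= 0):
            raise ValueError("volumes must be positive")
        if self.heats.size != self.injection_volumes.size:
            raise ValueError("one heat per injection required")


def _signal_coefficient(sp: SpeciesHydro, channel: Channel, pathlength: float) -> float:
    """Molar signal increment of one species for the given optical channel."""
    if channel == "absorbance280":
        if sp.extinction_280 is None:
            raise ValueError("absorbance channel requires extinction_280")
        return sp.extinction_280 * pathlength
    # interference: fringes = k_f * (mg/ml) * l; mol/L * (g/mol) = mg/ml
    return FRINGE_COEFF * sp.molar_mass * pathlength


def simulate_sv(
    species: Sequence[SpeciesHydro],
    cond: SolutionConditions,
    omega: float,
    scan_times: Sequence[float],
    geometry: CellGeometry = CellGeometry(),
    channel: Channel = "interference",
    noise_sigma: float = DEFAULT_NOISE,
    seed: int = 0,
    n_cells: int = 200,
) -> SVScanSet:
    """Simulate a sedimentation-velocity run of ideal, non-interacting species.

    Each species must carry (s, D) (use ``SpeciesHydro.with_transport`` to
    derive them from mass and f/f0) and a loading concentration in mol/L.
    Species signals are summed per channel and i.i.d. Gaussian noise of
    standard deviation ``noise_sigma`` is added.
    """
    if omega <= 0:
        raise ValueError("omega must be positive")
    mesh = LammMesh(geometry, n_cells)
    times = np.asarray(scan_times, float)
    total = np.zeros((times.size, mesh.centers.size))
    for sp in species:
        if sp.s is None or sp.diffusion is None:
            raise ValueError("species needs s and D set (see with_transport)")
        if sp.loading_concentration is None:
            raise ValueError("species needs a loading concentration")
        coeff = _signal_coefficient(sp, channel, geometry.pathlength)
        conc = solve_lamm(sp.s, sp.diffusion, omega, times, mesh,
                          c0=sp.loading_concentration)
        total += coeff * conc
    rng = np.random.default_rng(seed)
    if noise_sigma > 0:
        total = total + rng.normal(0.0, noise_sigma, size=total.shape)
    return SVScanSet(
        omega=omega, scan_times=times, radii=mesh.centers.copy(),
        signals=total, channel=channel, geometry=geometry,
        noise_sigma=noise_sigma,
    )


def se_sigma(molar_mass: float, vbar: float, omega: float,
             cond: SolutionConditions) -> float:
    """Reduced buoyant mass sigma = M (1 - vbar rho) w^2 / (R T), 1/cm^2."""
    from .constants import GAS_CONSTANT

    return (molar_mass * (1.0 - vbar * cond.density) * omega**2
            / (GAS_CONSTANT * cond.temperature))


def simulate_se(
    species: SpeciesHydro,
    cond: SolutionConditions,
    speeds_rpm: Sequence[float],
    loadings: Sequence[float],
    geometry: CellGeometry = CellGeometry(meniscus=6.9, base=7.2),
    channel: Channel = "interference",
    n_points: int = 60,
    noise_sigma: float = 0.004,
    seed: int = 0,
) -> SEProfileSet:
    """Simulate multi-speed sedimentation-equilibrium profiles.

    The equilibrium gradient of a single ideal species is
    ``c(r) = c(r0) exp[sigma (r^2 - r0^2) / 2]``; the amplitude is fixed by
    conserving the loading mass over the sector, so the simulated cell
    contains exactly the material that was loaded at rest.
    """
    rm, rb = geometry.meniscus, geometry.base
    radii = np.linspace(rm, rb, n_points)
    rng = np.random.default_rng(seed)
    profiles = []
    for rpm in speeds_rpm:
        omega = rpm_to_rad_s(rpm)
        sig = se_sigma(species.molar_mass, species.vbar, omega, cond)
        for c0 in loadings:
            shape = np.exp(sig * (radii**2 - rm**2) / 2.0)
            if abs(sig) < 1e-30:
                amplitude = c0
            else:
                # integral of exp(sig (r^2-rm^2)/2) r dr over [rm, rb]
                integral = (np.exp(sig * (rb**2 - rm**2) / 2.0) - 1.0) / sig
                amplitude = c0 * (rb**2 - rm**2) / 2.0 / integral
            conc = amplitude * shape
            coeff = _signal_coefficient(species, channel, geometry.pathlength)
            signal = coeff * conc
            if noise_sigma > 0:
                signal = signal + rng.normal(0.0, noise_sigma, size=signal.shape)
            profiles.append(SEProfile(omega=omega, loading=c0, radii=radii.copy(),
                                      signal=signal))
    return SEProfileSet(profiles=profiles, geometry=geometry, reference_radius=rm)


def simulate_binding_mixture(
    protein: SpeciesHydro,
    peptide: SpeciesHydro,
    ka: float,
    lt: float,
    pt: float,
    cond: SolutionConditions,
    omega: float,
    scan_times: Sequence[float],
    geometry: CellGeometry = BINDING_GEOMETRY,
    noise_sigma: float = DEFAULT_NOISE,
    seed: int = 0,
    n_cells: int = 200,
    sites_per_protein: int = 2,
) -> SVScanSet:
    """Simulate an absorbance-channel SV run of a protein/peptide mixture.

    The interaction is treated in the instantaneous-equilibrium
    (fast-exchange) limit: the peptide is partitioned once, at loading
    concentrations, between a free pool that sediments as the slow peptide
    species and a bound pool that co-sediments with the protein.  The bound
    pool's sedimentation coefficient is derived from the protein-plus-peptide
    mass at the protein's frictional ratio, producing the small upward shift
    of the fast boundary seen experimentally.

    Parameters
    ----------
    protein : SpeciesHydro
        The sedimenting macromolecule (here the obligate dimer, mass and
        extinction per dimer) with f/f0 set.
    peptide : SpeciesHydro
        The ligand, with f/f0 set and its own extinction.
    ka : float
        Site association constant, 1/M (0 allowed: no binding).
    lt, pt : float
        Total peptide and total binding sites (monomer-equivalent), mol/L.
    sites_per_protein : int
        Binding sites per sedimenting protein particle (2 for the dimer);
        converts site concentration ``pt`` to particle concentration.
    """
    if lt <= 0 or pt <= 0:
        raise ValueError("lt and pt must be positive")
    if ka < 0:
        raise ValueError("ka must be non-negative")
    pl = complex_concentration(ka, pt, lt)
    if ka > 0 and lt - pl < 1e-3 * lt:
        import warnings

        warnings.warn("binding saturated at loading concentrations; "
                      "theta rounds to 1 and the assay is uninformative")

    particle_conc = pt / sites_per_protein
    bound_per_particle = pl / particle_conc
    prot = protein.with_transport(cond)
    pep = peptide.with_transport(cond)

    species = []
    # free peptide pool
    species.append(SpeciesHydro(
        molar_mass=pep.molar_mass, vbar=pep.vbar, s=pep.s,
        diffusion=pep.diffusion, extinction_280=pep.extinction_280,
        loading_concentration=lt - pl,
    ))
    # protein particles (all of them), carrying the average bound peptide mass
    m_complex = prot.molar_mass + bound_per_particle * pep.molar_mass
    s_c, d_c = sD_from_M(m_complex, prot.ff0, prot.vbar, cond)
    eps_complex = (prot.extinction_280
                   + bound_per_particle * pep.extinction_280)
    species.append(SpeciesHydro(
        molar_mass=m_complex, vbar=prot.vbar, s=s_c, diffusion=d_c,
        extinction_280=eps_complex, loading_concentration=particle_conc,
    ))
    return simulate_sv(
        species, cond, omega, scan_times, geometry=geometry,
        channel="absorbance280", noise_sigma=noise_sigma, seed=seed,
        n_cells=n_cells,
    )


def simulate_itc(
    n: float,
    ka: float,
    dh: float,
    cell_volume: float = 0.2026,
    cell_concentration: float = 50e-6,
    syringe_concentration: float = 1e-3,
    injection_volumes: Optional[Sequence[float]] = None,
    noise_sigma: float = 0.1,
    proportional_noise: float = 0.0,
    seed: int = 0,
) -> ITCTitration:
    """Simulate a one-site ITC titration (heats in ucal per injection).

    Defaults follow the study protocol: 20 injections of 1 mM titrant into
    50 uM macromolecule in a 0.2026 ml cell.

    Parameters
    ----------
    n : float
        Stoichiometry (sites per macromolecule).
    ka : float
        Association constant, 1/M.
    dh : float
        Binding enthalpy, cal/mol of titrant.
    noise_sigma : float
        Additive Gaussian noise, ucal.
    proportional_noise : float
        Relative noise applied per injection heat (e.g. 0.02 for 2 %).
    """
    if injection_volumes is None:
        injection_volumes = np.full(20, 2e-3)  # ml
    vols = np.asarray(injection_volumes, float)
    heats = wiseman_injection_heats(
        n, ka, dh, cell_volume, cell_concentration, syringe_concentration, vols
    )
    rng = np.random.default_rng(seed)
    noisy = heats.copy()
    if proportional_noise > 0:
        noisy = noisy * (1.0 + rng.normal(0.0, proportional_noise, heats.size))
    if noise_sigma > 0:
        noisy = noisy + rng.normal(0.0, noise_sigma, heats.size)
    return ITCTitration(
        cell_volume=cell_volume,
        cell_concentration=cell_concentration,
        syringe_concentration=syringe_concentration,
        injection_volumes=vols,
        heats=noisy,
    )
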