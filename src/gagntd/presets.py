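"""Canonical species and run conditions of the Gag-NtD study.

The dimer parameters come from the published hydrodynamic table (sequence
monomer mass 22,713 g/mol, vbar 0.731 ml/g, eps280 19,200 1/(M cm), f/f0
1.48, buffer density 1.005 g/ml at 293.15 K).  The Env leader peptide is a
~20-residue peptide with eps280 11,400 1/(M cm) (two tryptophans); its mass
and shape are nominal values for a short unstructured peptide.
"""

import numpy as np

from .constants import rpm_to_rad_s
from .hydro import GAG_BUFFER, SpeciesHydro

MONOMER_MASS = 22_713.0  # g/mol, from sequence
DIMER_MASS = 2 * MONOMER_MASS
VBAR = 0.731  # ml/g
EPS_MONOMER = 19_200.0  # 1/(M cm)
EPS_PEPTIDE = 11_400.0  # 1/(M cm)

#: the obligate Gag-NtD dimer (extinction per dimer = 2 monomers)
GAG_NTD_DIMER = SpeciesHydro(
    molar_mass=DIMER_MASS, vbar=VBAR, ff0=1.48,
    extinction_280=2 * EPS_MONOMER,
)

#: Env leader peptide (nominal 20-mer: mass ~2.4 kDa, extended shape)
ENV_PEPTIDE = SpeciesHydro(
    molar_mass=2_400.0, vbar=0.72, ff0=1.2, extinction_280=EPS_PEPTIDE,
)

#: standard velocity-run protocol: 50,000 rpm, scans every 180 s
SV_OMEGA = rpm_to_rad_s(50_000)
SV_SCAN_INTERVAL = 180.0  # s

#: binding runs: 75 uM equimolar in 3 mm cells, absorbance at 280 nm
BINDING_LOADING = 75e-6  # mol/L
BINDING_CONDITIONS = GAG_BUFFER

#: equilibrium runs: short columns, three speeds (not printed in the study;
#: chosen in the usual range for a ~45 kDa species), loadings 14-100 uM
SE_SPEEDS_RPM = (10_000.0, 14_000.0, 20_000.0)
SE_LOADINGS = (14e-6, 50e-6, 100e-6)


def sv_scan_times(n_scans: int = 10, first: float = 1800.0,
                  interval: float = 6 * SV_SCAN_INTERVAL) -> np.ndarray:
    """A thinned scan schedule spanning the useful boundary movement of a
    ~3 S species at 50,000 rpm (instrument scans arrive every 180 s; every
    sixth is kept to keep fitted problems compact)."""
    return first + interval * np.arange(n_scans)
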