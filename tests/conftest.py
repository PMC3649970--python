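import pytest

from gagntd.hydro import GAG_BUFFER
from gagntd.presets import (
    BINDING_LOADING,
    ENV_PEPTIDE,
    GAG_NTD_DIMER,
    SV_OMEGA,
    VBAR,
    sv_scan_times,
)


@pytest.fixture(scope="session")
def buffer_conditions():
    return GAG_BUFFER


@pytest.fixture(scope="session")
def dimer():
    return GAG_NTD_DIMER


@pytest.fixture(scope="session")
def peptide():
    return ENV_PEPTIDE


@pytest.fixture(scope="session")
def scan_times():
    return sv_scan_times()


@pytest.fixture(scope="session")
def protein_scans(dimer, buffer_conditions, scan_times):
    """A noisy absorbance SV run of the dimer alone at the binding loading."""
    from gagntd import BINDING_GEOMETRY, simulate_sv

    sp = dimer.with_transport(buffer_conditions)
    sp.loading_concentration = BINDING_LOADING / 2  # sites -> dimer particles
    return simulate_sv(
        [sp], buffer_conditions, SV_OMEGA, scan_times,
        geometry=BINDING_GEOMETRY, channel="absorbance280",
        noise_sigma=0.006, seed=11,
    )


@pytest.fixture(scope="session")
def protein_cs(protein_scans, buffer_conditions):
    from gagntd import fit_cs

    return fit_cs(protein_scans, VBAR, buffer_conditions, ff0=1.48)
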