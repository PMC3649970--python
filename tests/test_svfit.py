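"""Inversion of SV data: C(S) distributions and discrete-species fits."""

import numpy as np
import pytest

from gagntd import (
    BINDING_GEOMETRY,
    CSDistribution,
    fit_cs,
    fit_discrete,
    integrate_peak,
    simulate_sv,
    weight_average_s,
)
from gagntd.hydro import SpeciesHydro
from gagntd.presets import SV_OMEGA, VBAR
from gagntd.svfit import estimate_noise

from gagntd.hydro import GAG_BUFFER
from gagntd.presets import GAG_NTD_DIMER

# s of the 45,426 g/mol dimer at f/f0 = 1.48 in the rho = 1.005 buffer
# (~3.03 S; the 20,w-corrected value in water is higher)
TRUE_S_SVEDBERG = GAG_NTD_DIMER.with_transport(GAG_BUFFER).s / 1e-13


@pytest.fixture(scope="module")
def noise_free_scans(dimer, buffer_conditions, scan_times):
    sp = dimer.with_transport(buffer_conditions)
    sp.loading_concentration = 37.5e-6
    return simulate_sv([sp], buffer_conditions, SV_OMEGA, scan_times,
                       geometry=BINDING_GEOMETRY, channel="absorbance280",
                       noise_sigma=0.0)


class TestFitCS:
    def test_single_species_peak_position(self, protein_cs):
        s_w = weight_average_s(protein_cs, 2.0, 4.0)
        assert abs(s_w - TRUE_S_SVEDBERG) <= 0.1  # one grid step

    def test_fit_rmsd_matches_injected_noise(self, protein_cs):
        assert protein_cs.fit_rmsd == pytest.approx(0.006, rel=0.25)

    def test_distribution_integral_conserves_loading_signal(self, protein_cs):
        total = protein_cs.total_signal()
        assert total == pytest.approx(2 * 19_200 * 0.3 * 37.5e-6, rel=0.02)

    def test_beer_lambert_window_integral(self, noise_free_scans, buffer_conditions):
        """Noise-free 3 S boundary integrates to eps * l * c."""
        csd = fit_cs(noise_free_scans, VBAR, buffer_conditions, ff0=1.48,
                     noise_target=1e-5)
        assert integrate_peak(csd, 2.0, 4.0) == pytest.approx(
            2 * 19_200 * 0.3 * 37.5e-6, rel=0.01
        )

    def test_noise_free_signal_concentrates_near_truth(
        self, noise_free_scans, buffer_conditions
    ):
        csd = fit_cs(noise_free_scans, VBAR, buffer_conditions, ff0=1.48,
                     noise_target=1e-5)
        near = integrate_peak(csd, TRUE_S_SVEDBERG - 0.3, TRUE_S_SVEDBERG + 0.3)
        assert near >= 0.95 * csd.total_signal()

    def test_regularisation_path_monotone_and_peak_stable(
        self, protein_scans, buffer_conditions
    ):
        """rmsd grows with regularisation strength; the peak moves less than
        one grid step over a 10x strength range."""
        base = fit_cs(protein_scans, VBAR, buffer_conditions, ff0=1.48)
        alphas = base.regularization * np.array([1.0, 3.0, 10.0])
        fits = [fit_cs(protein_scans, VBAR, buffer_conditions, ff0=1.48,
                       regularization=a) for a in alphas]
        rmsds = [f.fit_rmsd for f in fits]
        assert np.all(np.diff(rmsds) >= -1e-12)
        peaks = [weight_average_s(f, 2.0, 4.0) for f in fits]
        assert max(peaks) - min(peaks) <= 0.1

    def test_over_regularisation_warns_on_empty_solution(
        self, protein_scans, buffer_conditions
    ):
        with pytest.warns(UserWarning, match="over-regularised"):
            fit_cs(protein_scans, VBAR, buffer_conditions, ff0=1.48,
                   regularization=1e12)

    def test_interference_channel_with_ti_offsets_recovered(
        self, dimer, buffer_conditions, scan_times
    ):
        """A static radial offset pattern (interference artefact) does not
        disturb the recovered boundary when TI-noise projection is on."""
        sp = dimer.with_transport(buffer_conditions)
        sp.loading_concentration = 10e-6
        scans = simulate_sv([sp], buffer_conditions, SV_OMEGA, scan_times,
                            channel="interference", noise_sigma=0.004, seed=7)
        rng = np.random.default_rng(0)
        ti = 0.05 * np.sin(scans.radii * 40.0) + rng.normal(0, 0.02, scans.radii.size)
        scans.signals = scans.signals + ti[None, :]
        csd = fit_cs(scans, VBAR, buffer_conditions, ff0=1.48)
        s_w = weight_average_s(csd, 2.0, 4.0)
        assert abs(s_w - TRUE_S_SVEDBERG) <= 0.1


def test_outer_ff0_optimisation_recovers_shape(noise_free_scans,
                                               buffer_conditions):
    """The 1-D f/f0 search locates the simulated frictional ratio (coarse
    grid on noise-free data; a compact s-grid keeps the search cheap)."""
    from gagntd import fit_cs_ff0

    grid = np.round(np.arange(1.0, 6.01, 0.25), 9)
    best = fit_cs_ff0(noise_free_scans, VBAR, buffer_conditions,
                      ff0_bounds=(1.15, 2.2), n_eval=6, s_grid=grid,
                      noise_target=1e-5, n_cells=120)
    assert best.ff0 == pytest.approx(1.48, abs=0.15)


class TestIntegratePeak:
    def test_whole_grid_returns_total(self, protein_cs):
        whole = integrate_peak(protein_cs, protein_cs.s_grid[0],
                               protein_cs.s_grid[-1])
        assert whole == pytest.approx(protein_cs.total_signal())

    def test_empty_window_is_zero_with_warning(self, protein_cs):
        with pytest.warns(UserWarning, match="window"):
            assert integrate_peak(protein_cs, 11.0, 12.0) == 0.0

    def test_signal_free_window_is_negligible(self, protein_cs):
        assert integrate_peak(protein_cs, 6.0, 9.0) < 0.01 * protein_cs.total_signal()


class TestFitDiscrete:
    def test_noise_free_self_inversion(self, noise_free_scans, buffer_conditions):
        fit = fit_discrete(noise_free_scans, 1, VBAR, buffer_conditions,
                           s_guesses=[2.5], mass_guesses=[30_000.0])
        assert fit.rmsd < 1e-4
        assert fit.species[0].s == pytest.approx(TRUE_S_SVEDBERG, rel=1e-3)
        assert fit.species[0].molar_mass == pytest.approx(45_426.0, rel=1e-2)

    def test_noisy_single_species_recovery(self, protein_scans, buffer_conditions):
        fit = fit_discrete(protein_scans, 1, VBAR, buffer_conditions,
                           s_guesses=[2.5], mass_guesses=[30_000.0])
        assert fit.species[0].s == pytest.approx(TRUE_S_SVEDBERG, rel=0.01)
        assert fit.species[0].molar_mass == pytest.approx(45_426.0, rel=0.03)

    def test_two_well_separated_species(self, buffer_conditions, scan_times):
        # interference channel, 12 mm cell: both species carry ample signal
        slow = SpeciesHydro(molar_mass=8_000.0, vbar=0.72, ff0=1.3,
                            loading_concentration=30e-6)
        fast = SpeciesHydro(molar_mass=45_426.0, vbar=0.731, ff0=1.48,
                            loading_concentration=37.5e-6)
        slow_t = slow.with_transport(buffer_conditions)
        fast_t = fast.with_transport(buffer_conditions)
        scans = simulate_sv([slow_t, fast_t], buffer_conditions, SV_OMEGA,
                            scan_times, channel="interference",
                            noise_sigma=0.006, seed=21)
        fit = fit_discrete(scans, 2, VBAR, buffer_conditions,
                           s_guesses=[0.8, 2.6],
                           mass_guesses=[6_000.0, 30_000.0])
        s_true_slow = slow_t.s / 1e-13
        assert fit.species[0].s == pytest.approx(s_true_slow, rel=0.02)
        assert fit.species[1].s == pytest.approx(TRUE_S_SVEDBERG, rel=0.02)

    def test_discrete_and_cs_weight_average_agree(
        self, protein_scans, protein_cs, buffer_conditions
    ):
        fit = fit_discrete(protein_scans, 1, VBAR, buffer_conditions,
                           s_guesses=[2.5], mass_guesses=[30_000.0])
        s_cs = weight_average_s(protein_cs, 2.0, 4.0)
        assert fit.species[0].s == pytest.approx(s_cs, rel=0.01)


def test_noise_estimator_tracks_injected_sigma(protein_scans):
    assert estimate_noise(protein_scans) == pytest.approx(0.006, rel=0.15)


def test_csd_requires_increasing_grid():
    with pytest.raises(ValueError):
        CSDistribution(s_grid=np.array([1.0, 1.0, 2.0]),
                       amplitudes=np.zeros(3), ff0=1.4, regularization=0.0)
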