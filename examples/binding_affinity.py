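"""Association constant of the Gag-NtD / Env leader-peptide interaction.

The assay: sediment a 75 uM equimolar protein + peptide mixture in a 3 mm
cell recording absorbance at 280 nm, fit C(S), and compare the integrated
absorbance of the fast (3 S) boundary against a protein-only control.  The
gain equals the absorbance of co-sedimenting (bound) peptide, so

    theta = (A_mix - A_protein) / (eps_L * l * Lt)
    K_a   = theta / ((1 - theta)^2 * Lt)        (equimolar mass action)

Here the mixture is simulated at a known truth so the recovery can be seen.
"""

from gagntd import (
    BINDING_GEOMETRY,
    BindingExperiment,
    fit_cs,
    quantify_binding,
    simulate_binding_mixture,
    simulate_sv,
    theta_from_ka,
)
from gagntd.hydro import GAG_BUFFER
from gagntd.presets import ENV_PEPTIDE, GAG_NTD_DIMER, SV_OMEGA, VBAR, sv_scan_times

KA_TRUE = 1.3e5  # 1/M
LT = 75e-6  # mol/L, equimolar peptide and binding sites

times = sv_scan_times()
protein = GAG_NTD_DIMER.with_transport(GAG_BUFFER)
protein.loading_concentration = LT / 2  # dimer particles

control = simulate_sv([protein], GAG_BUFFER, SV_OMEGA, times,
                      geometry=BINDING_GEOMETRY, channel="absorbance280",
                      noise_sigma=0.006, seed=1)
mixture = simulate_binding_mixture(GAG_NTD_DIMER, ENV_PEPTIDE, KA_TRUE, LT, LT,
                                   GAG_BUFFER, SV_OMEGA, times,
                                   noise_sigma=0.006, seed=2)

csd_control = fit_cs(control, VBAR, GAG_BUFFER, ff0=1.48)
csd_mixture = fit_cs(mixture, VBAR, GAG_BUFFER, ff0=1.48)

result = quantify_binding(BindingExperiment(
    lt=LT, pt=LT, extinction_peptide=11_400.0, pathlength=0.3,
    csd_mixture=csd_mixture, csd_protein_only=csd_control,
))

print(f"truth:     K_a = {KA_TRUE:.2e} 1/M, theta = {theta_from_ka(KA_TRUE, LT):.3f}")
print(f"recovered: K_a = {result.ka:.2e} 1/M (+/- {result.ka_sigma:.1e}), "
      f"theta = {result.theta:.3f}, K_d = {result.kd * 1e6:.1f} uM")
print()
print("theta is the fraction of peptide co-sedimenting with the dimer;")
print("K_a follows from equimolar mass action at the loading concentration.")
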