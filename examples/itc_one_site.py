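"""One-site ITC analysis of the Gag-NtD / Env peptide interaction.

Simulates the study protocol (20 x 2 ul injections of 1 mM peptide into
50 uM protein in a 0.2026 ml cell) at a known truth and fits the Wiseman
one-site isotherm.  The c-value n*K*Mt0 ~ 7.5 sits inside the classic
fittable window, so n, K and dH are all identifiable.
"""

from gagntd import fit_itc, simulate_itc

N_TRUE, KA_TRUE, DH_TRUE = 1.0, 1.5e5, -8_000.0  # sites, 1/M, cal/mol

titration = simulate_itc(N_TRUE, KA_TRUE, DH_TRUE, noise_sigma=0.1,
                         proportional_noise=0.02, seed=3)
fit = fit_itc(titration, exclude_first=1)

print(f"truth:     n = {N_TRUE:.2f}, K_a = {KA_TRUE:.2e} 1/M, "
      f"dH = {DH_TRUE / 1e3:.1f} kcal/mol")
print(f"recovered: n = {fit.n:.2f}, K_a = {fit.ka:.2e} 1/M, "
      f"dH = {fit.dh / 1e3:.1f} kcal/mol")
print(f"K_d = {fit.kd * 1e6:.1f} uM, c-value = {fit.c_value:.1f}, "
      f"rmsd = {fit.rmsd:.2f} ucal")
thermo = fit.thermodynamics(293.15)
print(f"dG = {thermo['dG'] / 1e3:.1f} kcal/mol, "
      f"-TdS = {thermo['-TdS'] / 1e3:.1f} kcal/mol")
print()
print("n ~ 1 means one peptide per protein monomer; dG = -RT ln K_a splits")
print("into the fitted enthalpy and the entropic remainder.")
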