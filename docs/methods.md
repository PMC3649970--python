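# Methods

`gagntd` analyses the solution biophysics of the prototype foamy-virus
(PFV) Gag N-terminal domain (Gag-NtD), an obligate coiled-coil dimer, and
its interaction with the N-terminal leader peptide of the viral envelope
protein (Env-LP).  The package covers five measurement families:
hydrodynamic characterisation (sedimentation velocity and equilibrium),
co-sedimentation binding quantitation, one-site isothermal titration
calorimetry, structure-derived interface metrics, and the statistics of
two-colour restriction assays.  Because no raw instrument data are
distributed with the study, a forward-simulation layer generates every
input the analysis consumes under controlled, seeded noise; all recovery
claims in the test suite are claims about these synthetic conditions.

## Hydrodynamics

The core relations are the Svedberg equation and the anhydrous-sphere
frictional reference:

* `M = s R T / (D (1 - v̄ ρ))` connects the sedimentation coefficient `s`
  (seconds; 1 S = 1e-13 s), the diffusion coefficient `D` (cm²/s), the
  partial specific volume `v̄` (ml/g) and the solvent density `ρ` (g/ml)
  to the molar mass.
* the friction implied by `s` is `f = M (1 - v̄ρ) / (N_A s)`; by `D` it is
  `f = k_B T / D`.  Either is divided by the Stokes friction
  `f0 = 6π η r0`, `r0 = (3 M v̄ / 4 π N_A)^{1/3}`, of the *anhydrous*
  sphere of equal mass and volume (no hydration shell) to give `f/f0`.
  The anhydrous convention is deliberate: it reproduces the tabulated
  ratios of the study system to the printed precision, and any hydration
  correction would only rescale all ratios jointly.

Internally everything is CGS (cm, g, s, erg); the Svedberg appears only at
I/O boundaries.  `R = 8.31446e7 erg/(mol K)` and `N_A = 6.02214e23 /mol`
are fixed; `k_B` is *derived* as `R / N_A` rather than quoted
independently, because separately rounded constants disagree at the 1e-6
level and would break exact `M → (s, D) → M` round trips.  Two canned
solvent states are provided: water at 20 °C (`ρ = 0.99823`,
`η = 1.002e-2 P`) and the measurement buffer (`ρ = 1.005`, same
viscosity, 293.15 K).  `v̄` is always an input, never computed from
composition.

## Lamm-equation simulation

Sedimentation-velocity transport in a sector cell obeys the Lamm equation

    ∂c/∂t = (1/r) ∂/∂r [ r D ∂c/∂r − s ω² r² c ].

The solver is a conservative finite-volume discretisation on a uniform
radial mesh (default 200 cells over 6.0–7.2 cm) with Scharfetter–Gummel
(exponential-fitting) face fluxes and zero-flux ends.  This choice has
three consequences that the tests rely on:

* sector mass `∫ c r dr` is conserved to round-off by construction;
* the scheme degrades gracefully to upwinding in the advection-dominated
  limit, so the `D → 0` boundary tracks the meniscus characteristic
  `r_m exp(s ω² t)` to within one mesh cell;
* at protein-like Péclet numbers it is effectively central-difference
  accurate: simulated plateaus follow the radial square-dilution law
  `exp(−2 s ω² t)` to a few parts in 10⁴.

Time stepping is Crank–Nicolson with a short backward-Euler (Rannacher)
start to damp the meniscus start-up transient; the internal step keeps the
boundary displacement below half a cell per step.  A mesh/time
combination that would need more than 2×10⁵ steps is refused with a
diagnostic instead of silently returning an expensive or inaccurate
solution.  A uniform mesh (rather than a radially scaled one) was chosen
because at 200 cells over a 1.2 cm column the discretisation error is
already below the observation noise, which the grid-refinement test
checks directly.

Simulated velocity runs follow the study protocol: 50,000 rpm, scans on a
180 s instrument interval (thinned sixfold by default to keep fitted
problems compact — ten scans from 1800 s), interference optics for protein
characterisation (fringe coefficient 3.3 fringes·ml/(mg·cm), 12 mm path)
and absorbance optics in 3 mm cells for the binding runs.  The default
observation noise is σ = 0.006 signal units, the centre of the 0.004–0.008
rmsd band of the study's own C(S) fits.

## C(S) and discrete inversion

`fit_cs` regresses the scans against a dictionary of unit-loading Lamm
solutions, one per point of an s-grid (default 0.2–10 S in 0.1 S steps,
spanning free peptide to well past the dimer), with the diffusion
coefficient of each grid species tied to a shared frictional ratio.
The inversion is non-negative least squares with identity Tikhonov
regularisation.  The strength is set by the discrepancy principle — the
smallest strength whose residual rmsd reaches the noise estimate — rather
than by an F-statistic confidence level; the noise estimate itself comes
from a MAD-robust second-difference statistic of the scans, insensitive to
boundary curvature.  Time-invariant (per-radius) and radius-invariant
(per-scan) systematic offsets, inherent to interference optics, are
removed by algebraic projection of both data and dictionary before the
regression; the projection defaults on for interference and off for
absorbance data.  Radial margins near the meniscus (0.02 cm) and base
(0.08 cm) are excluded from all fits: the meniscus is optically distorted
in practice, and the back-diffusion pile-up at the base is steep,
poorly represented on any truncated s-grid, and carries no information
about boundary transport.  The distribution is stored as signal per
Svedberg, so its trapezoidal integral over a window is directly the
loading signal of the species inside the window.

An optional outer 1-D search (`fit_cs_ff0`) optimises the shared f/f0 on
a coarse-then-refined grid; the default keeps it fixed because the rmsd
surface in f/f0 is shallow and the binding quantitation does not depend
on it.

`fit_discrete` fits a small number of ideal species, each parameterised
by (s, M) with D eliminated through the Svedberg relation, amplitudes
solved by non-negative linear least squares inside the outer search
(variable projection).  On noise-free synthetic data it self-inverts to
solver tolerance.

## Binding quantitation

The co-sedimentation assay is modelled in the instantaneous-equilibrium
(fast-exchange) limit: at loading concentrations the peptide is
partitioned once by mass action between a free pool, which sediments as
the slow (~0.4 S) peptide species, and a bound pool co-sedimenting with
the dimer.  The bound pool's s comes from the protein-plus-bound-peptide
mass at the protein's frictional ratio, which produces the small upward
shift of the fast boundary seen experimentally.  A reacting
(kinetically coupled) Lamm system is deliberately out of scope: the
quantitation itself only assumes that the integrated fast-boundary
absorbance reports bound peptide at loading concentrations, so simulator
and estimator make the same physical assumption.

The estimator is the study's own arithmetic.  With equimolar totals
`Lt = Pt` (peptide and monomer-equivalent binding sites; the dimer carries
two independent sites), the fraction bound is

    θ = [A_mix(2–4 S) − A_protein(2–4 S)] / (ε_L · l · Lt)

and the association constant follows from mass action,

    K_a = θ / ((1 − θ)² Lt),       general form: K_a = θ / ((1 − θ)(Pt − θ Lt)).

`ε_L = 11,400 M⁻¹cm⁻¹` is assigned to the Env peptide (two tryptophans);
the protein's own absorbance cancels in the mixture-minus-control
difference.  The 2–4 S window is configurable; the free peptide sits far
below it.  θ outside [0, 1] from noise is clipped (with a hard error
beyond 2 % below zero, which indicates a mixture/control mismatch), and a
first-order uncertainty is propagated from the two C(S) fit rmsds through
the window integral and the derivative of the mass-action expression.
End-to-end on synthetic data at the study conditions (75 µM equimolar,
3 mm path, σ = 0.006) the pipeline recovers K_a = 1.3e5 and 2.0e4 M⁻¹
truths to within ~10 % in aggregate over seeds; the per-experiment spread
is of the same order, consistent with the propagated uncertainty.

The Env peptide's mass (2.4 kDa), v̄ (0.72 ml/g) and f/f0 (1.2) are
nominal values for a short, partly extended 20-mer; the quantitation is
insensitive to them because the free peptide lies outside the integration
window.

## Sedimentation equilibrium

A single ideal species at equilibrium follows
`A(r) = baseline + A(r₀) exp[M (1 − v̄ρ) ω² (r² − r₀²) / 2RT]` with r₀
fixed at the meniscus (any other choice only reparameterises the
amplitude).  Amplitude and baseline enter linearly, so fits are separable
and the outer search is 1-D in log M.  The global fit shares one M across
all speed × loading profiles with per-profile linear parameters.
Simulated gradients conserve the loaded material over the sector and use
three speeds (10, 14, 20 krpm — chosen in the usual range for a ~45 kDa
species; the study names no speeds) and loadings of 14–100 µM on a short
(0.3 cm) column.  Nine profiles at σ = 0.004–0.006 recover the dimer mass
well within 2 %.

## ITC

The forward model is the standard one-site (Wiseman) cumulative-heat
closed form with running concentrations following perfusion dilution of
an overfilled cell and per-injection heats corrected by the
displaced-volume term `(dV/V0)(Q_i + Q_{i−1})/2`.  Defaults mirror the
study protocol: 20 × 2 µl of 1 mM titrant into 50 µM macromolecule in a
0.2026 ml cell, giving c = n·K·Mt0 ≈ 7.5 at the measured affinity —
inside the fittable window.  The fit is nonlinear least squares over
(n, ln K, ΔH, heat offset) with the first injection excluded by default
(syringe-tip artefact convention).  Degenerate cases are flagged rather
than fitted through: a saturation heat indistinguishable from the
residual noise marks (n, K) unidentifiable, and c < 1 warns that the
isotherm is too shallow for a reliable K.  The synthetic truth uses
ΔH = −8 kcal/mol; the study prints no enthalpy, so recovery targets are
defined against this chosen truth, never against a claimed published
value.  Note one physical subtlety the tests document: the summed
injection heats approach the nominal capacity n·Mt0·V0·ΔH only to within
a few percent, because free macromolecule displaced from the active
volume before the equivalence point never binds.

## Structure metrics

Coordinates are parsed from PDB/mmCIF via gemmi into a flat atom table,
keeping the highest-occupancy alternate location per atom and dropping
waters, heteroatoms and hydrogens (the relevant crystal structures, at
2.4/2.9 Å, model no hydrogens).  Solvent-accessible surface area is
Shrake–Rupley with a deterministic golden-spiral sampling (960
points/atom by default, converged to < 1 %), probe 1.4 Å, and a
NACCESS-like element radii table (C 1.70, N 1.55, O 1.52, S 1.80 Å).
Buried interface area between chain sets is
`[SASA(A) + SASA(B) − SASA(AB)]`, reported both per monomer (halved — the
convention for a symmetric dimer interface) and as the total ΔASA, since
the published phrasing does not fully disambiguate the two.
Superposition is the Kabsch least-squares rotation with the proper-rotation
constraint; atoms are paired by (chain map, residue number, atom name),
Cα by default, restricted to residues present in both models.  Collinear
selections are rejected as rotationally unstable.

The deposited free (4JNH) and peptide-bound (4JMR) structures cannot be
redistributed inside this repository; the tests that reproduce the
published ~1700 Å² per-monomer interface and ~0.4 Å free-vs-bound Cα RMSD
look for `data/structures/4JNH.pdb` / `4JMR.pdb` and fail with
instructions when the files are absent.  All structure operations are
validated independently against closed forms (isolated-sphere area,
sphere-cap overlap, perturbation RMSD) and cross-checked against a second
implementation on synthetic models.

## Restriction statistics

The two-colour assay statistic is the ratio of the infection rate in
factor-positive cells to that in factor-negative cells, computed per
independent experiment and aggregated as mean ± sd (ratios first, then
averaged — matching per-experiment sd reporting).  Classification uses
the strict thresholds ratio < 0.3 = restricted, > 0.7 = not restricted;
boundary values fall in the intermediate band because the rule is stated
with strict inequalities.  Titres are normalised to the wild-type titre
of the same experiment (wild type ≡ 100 %), making the summary invariant
to per-experiment scale.

## What the synthetic data do and do not show

The simulators emulate ideal, non-interacting (or fast-exchange
two-pool) species with Gaussian observation noise at the study's rmsd
scale, known meniscus/base geometry, and exact buffer parameters.  They
do not emulate optical baseline drift beyond TI/RI offsets, meniscus
artefacts, concentration-dependent nonideality, slow binding kinetics,
or sample heterogeneity.  Passing recovery tests therefore demonstrates
that the estimators are unbiased and precise under the stated study
conditions — not that real-instrument systematics are handled; on real
data the meniscus position, in particular, would have to be fitted
rather than taken from the manifest.

## Numerical conventions

* Regularisation bisection runs on a logarithmic strength scale until the
  bracketing ratio falls below 5 %, against a noise target estimated
  robustly from the data unless supplied.
* Non-negative least squares is `scipy.optimize.nnls` on the
  Tikhonov-augmented system; outer nonlinear searches are
  `scipy.optimize.least_squares` (discrete SV, ITC) or bounded scalar
  minimisation on log M (SE).
* All simulators draw from `numpy.random.default_rng(seed)`; a fixed seed
  reproduces every dataset bit for bit.
* Integration windows and s-grids are rounded to 9 decimals so nominal
  window edges (2.0, 4.0 S) land exactly on grid points.
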