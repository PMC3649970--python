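"""Fraction-bound and association-constant quantitation from C(S) integrals.

For a 1:1 site interaction P + L <=> PL the fraction of bound peptide,
theta = [PL]/[Lt], follows mass action at the total (loading)
concentrations of peptide Lt and binding sites Pt:

    K_a = theta / ((1 - theta) (Pt - theta Lt))          (general)
    K_a = theta / ((1 - theta)^2 Lt)                      (equimolar, Lt = Pt)

In the sedimentation assay theta is measured from the gain in integrated
absorbance of the fast (protein) boundary of an equimolar mixture over the
protein-only control, divided by the total peptide absorbance
eps_L * l * Lt that would co-sediment at saturation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np


class SuperStoichiometricError(ValueError):
    """theta * Lt >= Pt: more peptide bound than sites available."""


def complex_concentration(ka: float, pt: float, lt: float) -> float:
    """[PL] at equilibrium from total sites ``pt`` and total ligand ``lt``.

    Solves K_a = [PL] / (([Pt]-[PL]) ([Lt]-[PL])), the root of the
    mass-action quadratic on [0, min(pt, lt)].
    """
    if ka < 0:
        raise ValueError("ka must be non-negative")
    if ka == 0:
        return 0.0
    b = pt + lt + 1.0 / ka
    disc = b * b - 4.0 * pt * lt
    return (b - np.sqrt(disc)) / 2.0


def theta_from_ka(ka: float, lt: float) -> float:
    """Equimolar fraction bound: the root of K_a Lt (1 - theta)^2 = theta."""
    return complex_concentration(ka, lt, lt) / lt


def ka_general(theta: float, lt: float, pt: float) -> float:
    """Association constant from theta with arbitrary Lt, Pt (1/M)."""
    if not 0.0 <= theta < 1.0:
        raise ValueError("theta must lie in [0, 1)")
    free_sites = pt - theta * lt
    if free_sites <= 0:
        raise SuperStoichiometricError(
            f"theta*Lt = {theta * lt:.3g} >= Pt = {pt:.3g}: "
            "bound ligand exceeds available sites"
        )
    return theta / ((1.0 - theta) * free_sites)


def ka_equimolar(theta: float, lt: float) -> float:
    """Association constant for the equimolar case, K_a = theta/((1-theta)^2 Lt)."""
    if not 0.0 <= theta <= 1.0:
        raise ValueError("theta must lie in [0, 1]")
    if theta == 1.0:
        warnings.warn("theta = 1: binding saturated, K_a unbounded")
        return np.inf
    return theta / ((1.0 - theta) ** 2 * lt)


@dataclass
class BindingExperiment:
    """An equimolar co-sedimentation binding measurement.

    ``csd_mixture`` and ``csd_protein_only`` are C(S) distributions fitted
    to absorbance-channel data at matched loading; the peak window (in
    Svedberg) selects the fast protein boundary.
    """

    lt: float  # total peptide, mol/L
    pt: float  # total binding sites (monomer-equivalent), mol/L
    extinction_peptide: float  # 1/(M cm)
    pathlength: float  # cm
    csd_mixture: "CSDistribution"
    csd_protein_only: "CSDistribution"
    peak_window: tuple[float, float] = (2.0, 4.0)

    def __post_init__(self) -> None:
        if self.lt <= 0 or self.pt <= 0:
            raise ValueError("lt and pt must be positive")
        if self.extinction_peptide <= 0 or self.pathlength <= 0:
            raise ValueError("extinction and pathlength must be positive")


@dataclass
class BindingResult:
    theta: float
    ka: float
    theta_sigma: Optional[float] = None
    ka_sigma: Optional[float] = None

    @property
    def kd(self) -> float:
        return np.inf if self.ka == 0 else 1.0 / self.ka


def bound_fraction(exp: BindingExperiment) -> float:
    """Fraction of peptide co-sedimenting with the protein boundary.

    theta = (A_mix - A_protein) / (eps_L * l * Lt), where both integrated
    absorbances are taken over the same s-window.  Values slightly outside
    [0, 1] from noise are clipped; clipping beyond 2 % raises.
    """
    from .svfit import integrate_peak

    lo, hi = exp.peak_window
    a_mix = integrate_peak(exp.csd_mixture, lo, hi)
    a_prot = integrate_peak(exp.csd_protein_only, lo, hi)
    denom = exp.extinction_peptide * exp.pathlength * exp.lt
    theta = (a_mix - a_prot) / denom
    if theta < -0.02:
        raise ValueError(
            f"raw theta = {theta:.3f} < 0 beyond noise tolerance: "
            "mixture/control mismatch"
        )
    if theta > 1.02:
        warnings.warn(f"raw theta = {theta:.3f} clipped to 1")
    return float(np.clip(theta, 0.0, 1.0))


def quantify_binding(exp: BindingExperiment) -> BindingResult:
    """theta and K_a (with first-order uncertainty) from a binding experiment.

    Uses the equimolar reduction when Lt = Pt (within 1 ppm), the general
    expression otherwise.  The theta uncertainty is propagated from the two
    C(S) fit rmsd values through the integral (treating the per-point noise
    as independent over the fitted radial points) and mapped to K_a by the
    derivative of the mass-action expression.
    """
    theta = bound_fraction(exp)
    equimolar = abs(exp.lt - exp.pt) <= 1e-6 * exp.lt
    if equimolar:
        ka = ka_equimolar(theta, exp.lt)
    else:
        ka = ka_general(theta, exp.lt, exp.pt)

    theta_sigma = None
    ka_sigma = None
    rmsds = [exp.csd_mixture.fit_rmsd, exp.csd_protein_only.fit_rmsd]
    if all(r is not None for r in rmsds):
        # each integral inherits ~ rmsd * sqrt(window width * grid step)
        denom = exp.extinction_peptide * exp.pathlength * exp.lt
        lo, hi = exp.peak_window
        width = hi - lo
        var = sum((r * np.sqrt(width)) ** 2 for r in rmsds)
        theta_sigma = float(np.sqrt(var) / denom)
        if theta < 1.0:
            if equimolar:
                # d/dtheta [theta / ((1-theta)^2 Lt)]
                dka = (1.0 + theta) / ((1.0 - theta) ** 3 * exp.lt)
            else:
                free = exp.pt - theta * exp.lt
                dka = (free + (1.0 - theta) * exp.lt * theta / free) / (
                    (1.0 - theta) ** 2 * free
                )
            ka_sigma = float(abs(dka) * theta_sigma)
    return BindingResult(theta=theta, ka=float(ka), theta_sigma=theta_sigma,
                         ka_sigma=ka_sigma)
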