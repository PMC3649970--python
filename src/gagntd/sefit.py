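"""Sedimentation-equilibrium analysis: single-profile and global fits.

A single ideal species at equilibrium follows

    A(r) = baseline + A(r0) * exp[ M (1 - vbar rho) w^2 (r^2 - r0^2) / (2 R T) ]

with the reference radius r0 fixed at the meniscus.  The amplitude and
baseline enter linearly, so fits are separable: for any trial mass the
linear pair is solved in closed form and the outer search is 1-D in M.
The global fit shares one M across all profiles (speeds x loadings) with
per-profile amplitudes and baselines, exactly the multi-speed strategy
used to extract a final weight-averaged molecular mass.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import minimize_scalar

from .constants import GAS_CONSTANT
from .hydro import SolutionConditions
from .simulate import SEProfile, SEProfileSet


@dataclass
class SEFitSingle:
    molar_mass: float
    amplitude: float  # signal at the reference radius
    baseline: float
    rmsd: float
    converged: bool
    non_sedimenting: bool = False


@dataclass
class GlobalSEFit:
    molar_mass: float
    amplitudes: np.ndarray  # per profile
    baselines: np.ndarray
    rmsds: np.ndarray
    pooled_rmsd: float
    converged: bool


def _design(profile: SEProfile, mass: float, vbar: float,
            cond: SolutionConditions, r0: float) -> np.ndarray:
    sig = (mass * (1.0 - vbar * cond.density) * profile.omega**2
           / (GAS_CONSTANT * cond.temperature))
    return np.exp(sig * (profile.radii**2 - r0**2) / 2.0)


def _linear_solve(profile: SEProfile, mass: float, vbar: float,
                  cond: SolutionConditions, r0: float,
                  fit_baseline: bool = True) -> tuple[float, float, float]:
    """(amplitude, baseline, sse) at fixed mass -- the separable inner fit."""
    e = _design(profile, mass, vbar, cond, r0)
    if fit_baseline:
        a = np.column_stack([e, np.ones_like(e)])
    else:
        a = e[:, None]
    coef, *_ = np.linalg.lstsq(a, profile.signal, rcond=None)
    resid = profile.signal - a @ coef
    baseline = float(coef[1]) if fit_baseline else 0.0
    return float(coef[0]), baseline, float(resid @ resid)


def fit_se_single(
    profile: SEProfile,
    vbar: float,
    cond: SolutionConditions,
    mass_bounds: tuple[float, float] = (100.0, 1e7),
    reference_radius: Optional[float] = None,
    fit_baseline: bool = True,
) -> SEFitSingle:
    """Least-squares single-species fit of one equilibrium profile."""
    if profile.radii.size < 20:
        raise ValueError("need at least 20 radial points")
    r0 = profile.radii[0] if reference_radius is None else reference_radius

    def sse(log_m: float) -> float:
        return _linear_solve(profile, np.exp(log_m), vbar, cond, r0,
                             fit_baseline)[2]

    res = minimize_scalar(sse, bounds=(np.log(mass_bounds[0]), np.log(mass_bounds[1])),
                          method="bounded", options={"xatol": 1e-10})
    mass = float(np.exp(res.x))
    amp, base, s = _linear_solve(profile, mass, vbar, cond, r0, fit_baseline)
    rmsd = float(np.sqrt(s / profile.radii.size))
    # a flat profile is fit entirely by the baseline: the exponential term
    # carries no signal above the noise, whatever mass the search settled on
    e = _design(profile, mass, vbar, cond, r0)
    model_range = abs(amp) * (e.max() - e.min())
    non_sed = model_range < 5.0 * rmsd + 1e-12
    if non_sed:
        warnings.warn("profile is flat: species appears non-sedimenting")
    return SEFitSingle(molar_mass=mass, amplitude=amp, baseline=base, rmsd=rmsd,
                       converged=bool(res.success), non_sedimenting=non_sed)


def fit_se_global(
    profiles: SEProfileSet,
    vbar: float,
    cond: SolutionConditions,
    mass_bounds: tuple[float, float] = (100.0, 1e7),
    fit_baseline: bool = True,
) -> GlobalSEFit:
    """Global single-species fit: one shared M, per-profile amplitude/baseline."""
    if len(profiles) < 2:
        raise ValueError("global fit needs at least 2 profiles")
    r0 = profiles.reference_radius
    plist = profiles.profiles
    geo = profiles.geometry
    for p in plist:
        if p.radii[0] < geo.meniscus - 1e-9 or p.radii[-1] > geo.base + 1e-9:
            raise ValueError("profile radii outside the stated cell geometry")

    def total_sse(log_m: float) -> float:
        m = np.exp(log_m)
        return sum(_linear_solve(p, m, vbar, cond, r0, fit_baseline)[2]
                   for p in plist)

    res = minimize_scalar(total_sse,
                          bounds=(np.log(mass_bounds[0]), np.log(mass_bounds[1])),
                          method="bounded", options={"xatol": 1e-10})
    mass = float(np.exp(res.x))
    amps, bases, rmsds = [], [], []
    n_tot, sse_tot = 0, 0.0
    for p in plist:
        amp, base, s = _linear_solve(p, mass, vbar, cond, r0, fit_baseline)
        amps.append(amp)
        bases.append(base)
        rmsds.append(np.sqrt(s / p.radii.size))
        n_tot += p.radii.size
        sse_tot += s
    return GlobalSEFit(
        molar_mass=mass,
        amplitudes=np.array(amps),
        baselines=np.array(bases),
        rmsds=np.array(rmsds),
        pooled_rmsd=float(np.sqrt(sse_tot / n_tot)),
        converged=bool(res.success),
    )
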