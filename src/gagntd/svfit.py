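"""Inversion of sedimentation-velocity data: discrete species and C(S).

Two analyses mirror standard SV-AUC practice:

* ``fit_discrete`` -- nonlinear least squares of a small number of ideal
  species, each parameterised by (s, M, loading signal), with diffusion
  tied to s and M through the Svedberg relation.  Amplitudes are solved
  by non-negative linear least squares inside the outer nonlinear search
  (variable projection).

* ``fit_cs`` -- a continuous distribution c(s) over an s-grid: the data are
  regressed against a dictionary of normalised Lamm solutions (one per grid
  point, with D derived from a shared frictional ratio), under
  non-negativity and Tikhonov regularisation.  The regularisation strength
  is chosen by the discrepancy principle: the smallest strength whose
  residual rmsd reaches the estimated noise level.  Time-invariant and
  radius-invariant systematic offsets (inherent to interference optics) can
  be removed by algebraic projection before the regression.

The integral of c(s) over the grid equals the total fitted loading signal,
so boundary absorbances are read off with ``integrate_peak``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares, nnls

from .constants import SVEDBERG
from .hydro import SolutionConditions, d_from_s_ff0
from .lamm import LammMesh, solve_lamm
from .simulate import SVScanSet


@dataclass
class CSDistribution:
    """c(s): signal per Svedberg over a strictly increasing s-grid (Svedberg)."""

    s_grid: np.ndarray
    amplitudes: np.ndarray
    ff0: float
    regularization: float
    fit_rmsd: Optional[float] = None

    def __post_init__(self) -> None:
        self.s_grid = np.asarray(self.s_grid, float)
        self.amplitudes = np.asarray(self.amplitudes, float)
        if np.any(np.diff(self.s_grid) <= 0):
            raise ValueError("s_grid must be strictly increasing")
        if self.s_grid.shape != self.amplitudes.shape:
            raise ValueError("grid/amplitude shape mismatch")

    def total_signal(self) -> float:
        return float(np.trapezoid(self.amplitudes, self.s_grid))


@dataclass
class DiscreteSpecies:
    s: float  # Svedberg
    molar_mass: float  # g/mol
    signal: float  # loading signal units


@dataclass
class DiscreteFit:
    species: list[DiscreteSpecies]
    rmsd: float
    converged: bool
    s_stderr: Optional[np.ndarray] = None


def default_s_grid(lo: float = 0.2, hi: float = 10.0, step: float = 0.1) -> np.ndarray:
    """Default s-grid, Svedberg: covers free peptide (~0.3 S) to well past 3 S."""
    # rounded so window edges like 2.0 and 4.0 land exactly on grid points
    return np.round(np.arange(lo, hi + step / 2, step), 9)


def integrate_peak(csd: CSDistribution, s_lo: float, s_hi: float) -> float:
    """Trapezoidal integral of c(s) ds over [s_lo, s_hi] (signal units)."""
    s, c = csd.s_grid, csd.amplitudes
    mask = (s >= s_lo) & (s <= s_hi)
    if mask.sum() < 2:
        warnings.warn(f"integration window [{s_lo}, {s_hi}] S contains "
                      f"{int(mask.sum())} grid points; returning 0")
        return 0.0
    return float(np.trapezoid(c[mask], s[mask]))


def weight_average_s(csd: CSDistribution, s_lo: float, s_hi: float) -> float:
    """Signal-weighted mean s over a window (Svedberg)."""
    s, c = csd.s_grid, csd.amplitudes
    mask = (s >= s_lo) & (s <= s_hi)
    w = np.trapezoid(c[mask], s[mask])
    if w <= 0:
        raise ValueError("no signal in window")
    return float(np.trapezoid(c[mask] * s[mask], s[mask]) / w)


# ---------------------------------------------------------------------------
# Lamm dictionary (cached: rebuilding it dominates C(S) cost)

_DICTIONARY_CACHE: dict[tuple, np.ndarray] = {}


def _lamm_dictionary(
    s_grid: np.ndarray,
    ff0: float,
    vbar: float,
    cond: SolutionConditions,
    scans: SVScanSet,
    n_cells: int,
) -> np.ndarray:
    """(n_scans * n_radii, n_s) matrix of unit-loading Lamm solutions."""
    key = (
        tuple(np.round(s_grid, 6)), round(ff0, 6), round(vbar, 6),
        (cond.temperature, cond.density, cond.viscosity),
        (scans.geometry.meniscus, scans.geometry.base),
        tuple(np.round(scans.scan_times, 3)), scans.omega, n_cells,
        tuple(np.round(scans.radii[[0, -1]], 9)), scans.radii.size,
    )
    if key in _DICTIONARY_CACHE:
        return _DICTIONARY_CACHE[key]
    mesh = LammMesh(scans.geometry, n_cells)
    cols = []
    for s_sved in s_grid:
        s = s_sved * SVEDBERG
        d = d_from_s_ff0(s, ff0, vbar, cond)
        prof = solve_lamm(s, d, scans.omega, scans.scan_times, mesh, c0=1.0)
        if not np.array_equal(mesh.centers, scans.radii):
            prof = np.vstack([
                np.interp(scans.radii, mesh.centers, row) for row in prof
            ])
        cols.append(prof.ravel())
    mat = np.column_stack(cols)
    _DICTIONARY_CACHE[key] = mat
    return mat


def estimate_noise(scans: SVScanSet, signals: Optional[np.ndarray] = None) -> float:
    """Noise sigma from radial second differences of the scans.

    Uses a MAD-based robust scale so the steep back-diffusion region near
    the base (or any residual boundary curvature) does not inflate the
    estimate."""
    sig = scans.signals if signals is None else signals
    d2 = np.diff(sig, n=2, axis=1)
    mad = np.median(np.abs(d2 - np.median(d2)))
    return float(1.4826 * mad / np.sqrt(6.0))


def _radial_mask(scans: SVScanSet, margin_meniscus: float,
                 margin_base: float) -> np.ndarray:
    g = scans.geometry
    mask = ((scans.radii >= g.meniscus + margin_meniscus)
            & (scans.radii <= g.base - margin_base))
    if mask.sum() < 10:
        raise ValueError("fit margins leave fewer than 10 radial points")
    return mask


def _projection_ti_ri(y: np.ndarray, n_scans: int, n_radii: int,
                      ti: bool, ri: bool) -> np.ndarray:
    """Project out time-invariant (per-radius) and radius-invariant
    (per-scan) offset subspaces from flattened scan data / dictionary columns."""
    z = y.reshape(n_scans, n_radii).astype(float)
    if ti:
        z = z - z.mean(axis=0, keepdims=True)
    if ri:
        z = z - z.mean(axis=1, keepdims=True)
    return z.ravel()


def _solve_regularised(a: np.ndarray, y: np.ndarray, alpha: float) -> np.ndarray:
    n = a.shape[1]
    if alpha > 0:
        a_aug = np.vstack([a, np.sqrt(alpha) * np.eye(n)])
        y_aug = np.concatenate([y, np.zeros(n)])
    else:
        a_aug, y_aug = a, y
    x, _ = nnls(a_aug, y_aug)
    return x


def fit_cs(
    scans: SVScanSet,
    vbar: float,
    cond: SolutionConditions,
    ff0: float = 1.48,
    s_grid: Optional[np.ndarray] = None,
    regularization: Optional[float] = None,
    noise_target: Optional[float] = None,
    remove_ti_noise: Optional[bool] = None,
    remove_ri_noise: bool = False,
    n_cells: int = 200,
    margin_meniscus: float = 0.02,
    margin_base: float = 0.08,
) -> CSDistribution:
    """Fit a continuous sedimentation-coefficient distribution to SV scans.

    Parameters
    ----------
    ff0 : float
        Shared frictional ratio that maps each grid s to a diffusion
        coefficient (fixed here; see ``fit_cs_ff0`` to optimise it).
    regularization : float, optional
        Explicit Tikhonov strength.  If omitted, chosen by the discrepancy
        principle against ``noise_target`` (estimated from the data when not
        given).
    remove_ti_noise : bool, optional
        Project out per-radius time-invariant offsets; defaults to True for
        interference data and False for absorbance.
    margin_meniscus, margin_base : float
        Radial margins (cm) excluded from the fit: optical artefacts at the
        meniscus and the steep back-diffusion pile-up at the base.
    """
    if s_grid is None:
        s_grid = default_s_grid()
    if remove_ti_noise is None:
        remove_ti_noise = scans.channel == "interference"
    rmask = _radial_mask(scans, margin_meniscus, margin_base)
    a_full = _lamm_dictionary(s_grid, ff0, vbar, cond, scans, n_cells)
    n_scans, n_radii = scans.signals.shape
    masked = scans.signals[:, rmask]
    y = masked.ravel().astype(float)
    n_fit = int(rmask.sum())
    a = a_full.reshape(n_scans, n_radii, -1)[:, rmask, :].reshape(
        n_scans * n_fit, -1)
    if remove_ti_noise or remove_ri_noise:
        y = _projection_ti_ri(y, n_scans, n_fit, remove_ti_noise, remove_ri_noise)
        a = np.column_stack([
            _projection_ti_ri(col, n_scans, n_fit, remove_ti_noise,
                              remove_ri_noise)
            for col in a.T
        ])

    def rmsd_of(x: np.ndarray) -> float:
        return float(np.sqrt(np.mean((a @ x - y) ** 2)))

    col_scale = float(np.mean(np.sum(a * a, axis=0)))
    if regularization is not None:
        alpha = regularization
        x = _solve_regularised(a, y, alpha)
    else:
        target = (noise_target if noise_target is not None
                  else estimate_noise(scans, masked))
        lo, hi = 1e-10 * col_scale, 1e2 * col_scale
        x_lo = _solve_regularised(a, y, lo)
        if rmsd_of(x_lo) >= target:
            alpha, x = lo, x_lo  # cannot reach the target; least-regularised fit
        else:
            for _ in range(40):
                mid = np.sqrt(lo * hi)
                x_mid = _solve_regularised(a, y, mid)
                if rmsd_of(x_mid) < target:
                    lo = mid
                else:
                    hi = mid
                if hi / lo < 1.05:
                    break
            alpha = lo
            x = _solve_regularised(a, y, alpha)
    fitted_rms = float(np.sqrt(np.mean((a @ x) ** 2)))
    data_rms = float(np.sqrt(np.mean(y**2)))
    if data_rms > 0 and fitted_rms < 0.01 * data_rms:
        warnings.warn("near-zero C(S): over-regularised or empty signal")
    step = np.gradient(s_grid)
    return CSDistribution(
        s_grid=s_grid, amplitudes=x / step, ff0=ff0, regularization=float(alpha),
        fit_rmsd=rmsd_of(x),
    )


def fit_cs_ff0(
    scans: SVScanSet,
    vbar: float,
    cond: SolutionConditions,
    ff0_bounds: tuple[float, float] = (1.1, 2.5),
    n_eval: int = 8,
    **kwargs,
) -> CSDistribution:
    """C(S) with a coarse outer 1-D optimisation of the shared f/f0.

    Evaluates the regularised fit on a grid of frictional ratios and refines
    once around the best point; adequate because rmsd varies slowly in f/f0.
    """
    lo, hi = ff0_bounds

    def run(ff0: float) -> CSDistribution:
        return fit_cs(scans, vbar, cond, ff0=ff0, **kwargs)

    grid = np.linspace(lo, hi, n_eval)
    fits = [run(f) for f in grid]
    i = int(np.argmin([f.fit_rmsd for f in fits]))
    lo2 = grid[max(i - 1, 0)]
    hi2 = grid[min(i + 1, n_eval - 1)]
    grid2 = np.linspace(lo2, hi2, 5)
    fits2 = [run(f) for f in grid2]
    j = int(np.argmin([f.fit_rmsd for f in fits2]))
    return fits2[j]


# ---------------------------------------------------------------------------
# discrete-species analysis


def fit_discrete(
    scans: SVScanSet,
    n_species: int,
    vbar: float,
    cond: SolutionConditions,
    s_guesses: Sequence[float],
    mass_guesses: Sequence[float],
    n_cells: int = 200,
    margin_meniscus: float = 0.02,
    margin_base: float = 0.08,
) -> DiscreteFit:
    """Fit ``n_species`` ideal species to SV scans (variable projection).

    ``s_guesses`` in Svedberg, ``mass_guesses`` in g/mol.  For each species
    D follows from (s, M) through the Svedberg relation; loading signals are
    solved by non-negative linear least squares at every step of the outer
    search over (s, log M).
    """
    if scans.scan_times.size < 2:
        raise ValueError("need at least 2 scans spanning boundary movement")
    if len(s_guesses) != n_species or len(mass_guesses) != n_species:
        raise ValueError("one (s, M) guess per species required")
    from .constants import GAS_CONSTANT
    from .hydro import buoyancy

    mesh = LammMesh(scans.geometry, n_cells)
    rmask = _radial_mask(scans, margin_meniscus, margin_base)
    y = scans.signals[:, rmask].ravel().astype(float)
    buoy = buoyancy(vbar, cond)

    def columns(params: np.ndarray) -> np.ndarray:
        cols = []
        for k in range(n_species):
            s = params[2 * k] * SVEDBERG
            m = np.exp(params[2 * k + 1])
            d = s * GAS_CONSTANT * cond.temperature / (m * buoy)
            prof = solve_lamm(s, d, scans.omega, scans.scan_times, mesh, c0=1.0)
            if not np.array_equal(mesh.centers, scans.radii):
                prof = np.vstack([
                    np.interp(scans.radii, mesh.centers, row) for row in prof
                ])
            cols.append(prof[:, rmask].ravel())
        return np.column_stack(cols)

    def residuals(params: np.ndarray) -> np.ndarray:
        a = columns(params)
        amps, _ = nnls(a, y)
        return a @ amps - y

    p0 = np.empty(2 * n_species)
    p0[0::2] = np.asarray(s_guesses, float)
    p0[1::2] = np.log(np.asarray(mass_guesses, float))
    lower = np.empty_like(p0)
    upper = np.empty_like(p0)
    lower[0::2] = 0.05
    upper[0::2] = 100.0
    lower[1::2] = np.log(100.0)
    upper[1::2] = np.log(1e8)
    res = least_squares(residuals, p0, bounds=(lower, upper),
                        diff_step=1e-4, max_nfev=200)
    a = columns(res.x)
    amps, _ = nnls(a, y)
    rmsd = float(np.sqrt(np.mean((a @ amps - y) ** 2)))
    order = np.argsort(res.x[0::2])
    species = [
        DiscreteSpecies(s=float(res.x[2 * k]), molar_mass=float(np.exp(res.x[2 * k + 1])),
                        signal=float(amps[k]))
        for k in order
    ]
    if not res.success:
        warnings.warn("discrete fit did not converge; best-so-far returned")
    # 1-sigma on s from the Gauss-Newton approximation
    s_stderr = None
    try:
        jtj = res.jac.T @ res.jac
        cov = np.linalg.pinv(jtj) * rmsd**2
        s_stderr = np.sqrt(np.maximum(np.diag(cov)[0::2], 0.0))[order]
    except np.linalg.LinAlgError:  # pragma: no cover
        pass
    return DiscreteFit(species=species, rmsd=rmsd, converged=bool(res.success),
                       s_stderr=s_stderr)
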