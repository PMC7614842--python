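"""Multivalent-bond kinetics of immune-complex (IC) retention on FDC membranes.

An IC carrying ``n_L`` accessible C3d ligands is held on a membrane patch
bearing ``n_R`` CR2 receptors by ``m`` closed bonds.  The number of closed
bonds performs a birth-death random walk with unbinding rate
``r(m) = m * k_off`` and rebinding rate ``g(m) = C(m) * k_on``, where the
configuration count ``C(m) = (n_R - m) (n_L - m)`` expresses the all-to-all
binding geometry (every free ligand can reach every free receptor within the
patch).  The state ``m = 0`` is absorbing (``g(0) = 0``): once all bonds are
open the IC leaves and never re-associates.

The chain is solved exactly through an eigendecomposition of the (symmetrized)
transient sub-generator, which makes survival curves available at arbitrary
times -- the relevant time span runs from fractions of a second (single-bond
lifetime 1/k_off ~ 7 s) to weeks.

Patch-level survival is averaged over a Poisson distribution of per-patch
receptor counts to describe a population of FDC membrane patches at a given
mean CR2 surface density, and ``<S(t)> * <n_R>`` is used as the mean IC
surface level.  ``calibrate_rebinding`` adjusts ``(k_on, n_L)`` so that the
model reproduces measured IC half-lives at known CR2 densities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.linalg import eigh_tridiagonal, expm
from scipy.optimize import brentq
from scipy.stats import poisson

from .errors import CalibrationError, GridTooShortError, InfeasibleAnchorsError

__all__ = [
    "DEFAULT_PATCH_AREA_UM2",
    "BondKineticsParams",
    "PatchSpec",
    "MasterEquationSolution",
    "SurvivalCurve",
    "CalibrationResult",
    "configuration_count",
    "default_time_grid",
    "solve_master_equation",
    "survival_probability",
    "poisson_mixture_survival",
    "ic_surface_level",
    "half_life",
    "mixture_level_at",
    "mixture_half_life",
    "density_to_mean_nR",
    "calibrate_rebinding",
]

#: Default membrane patch area (um^2).  The all-to-all configuration count
#: requires every C3d on the IC to reach every CR2 on the patch, so the patch
#: is the capture disc of a bound IC: radius ~ IC radius (~35 nm) + CR2
#: contour length (~40 nm) ~ 75 nm, area ~ pi * 0.075^2 ~ 0.018 um^2.
DEFAULT_PATCH_AREA_UM2 = 0.018


@dataclass(frozen=True)
class BondKineticsParams:
    """Rate constants and geometry of the multivalent bond model.

    Parameters
    ----------
    k_off
        Single-bond dissociation rate (s^-1).  From BLI this is 0.15 s^-1
        for CR2-C3dg; it sets the time unit of the model.
    k_on
        Effective per-configuration rebinding rate (s^-1).  This is a
        two-dimensional, membrane-confined rate and is deliberately distinct
        from the solution-phase association constant (M^-1 s^-1) measured by
        BLI; it is obtained by calibration against measured IC half-lives.
    n_L
        Number of accessible C3d ligand sites per IC (>= 1).
    patch_area
        Membrane patch area (um^2) used to convert CR2 surface densities
        into per-patch receptor counts.
    """

    k_off: float
    k_on: float
    n_L: int
    patch_area: float = DEFAULT_PATCH_AREA_UM2

    def __post_init__(self):
        if not self.k_off > 0:
            raise ValueError(f"k_off must be > 0, got {self.k_off}")
        if self.k_on < 0:
            raise ValueError(f"k_on must be >= 0, got {self.k_on}")
        if int(self.n_L) != self.n_L or self.n_L < 1:
            raise ValueError(f"n_L must be a positive integer, got {self.n_L}")
        if not self.patch_area > 0:
            raise ValueError(f"patch_area must be > 0, got {self.patch_area}")
        object.__setattr__(self, "n_L", int(self.n_L))


@dataclass(frozen=True)
class PatchSpec:
    """A single membrane patch with ``n_R`` CR2 receptors."""

    n_R: int

    def __post_init__(self):
        if int(self.n_R) != self.n_R or self.n_R < 0:
            raise ValueError(f"n_R must be a non-negative integer, got {self.n_R}")
        object.__setattr__(self, "n_R", int(self.n_R))


@dataclass(frozen=True)
class MasterEquationSolution:
    """Time-resolved bond-number distribution for one patch.

    ``P[m, k]`` is the probability of ``m`` closed bonds at ``times[k]``,
    for ``m`` in ``0..M`` with ``M = min(n_R, n_L)``.  At the first time
    point all mass sits at ``m = M`` (maximum bond formation).
    """

    times: np.ndarray
    P: np.ndarray
    n_R: int
    n_L: int

    @property
    def max_bonds(self) -> int:
        return min(self.n_R, self.n_L)


@dataclass(frozen=True)
class SurvivalCurve:
    """IC survival probability versus time.

    ``kind`` is ``"single"`` for a single-patch curve (``mean_n_R`` then
    holds the integer receptor count) or ``"poisson"`` for a curve averaged
    over a Poisson distribution of per-patch receptor counts.
    """

    times: np.ndarray
    S: np.ndarray
    mean_n_R: float
    kind: str = "single"

    def __post_init__(self):
        if self.kind not in ("single", "poisson"):
            raise ValueError(f"kind must be 'single' or 'poisson', got {self.kind!r}")


def configuration_count(m: int, n_R: int, n_L: int) -> int:
    """Number of open-bond pairings available for forming the next bond.

    All-to-all geometry: ``C(m) = (n_R - m) (n_L - m)``.  Vanishes when the
    receptors or the ligands are exhausted.
    """
    if m < 0 or m > min(n_R, n_L):
        raise ValueError(f"m={m} outside [0, min(n_R={n_R}, n_L={n_L})]")
    return (n_R - m) * (n_L - m)


def default_time_grid(t_min: float = 0.1, t_max: float = 2e7, n: int = 400) -> np.ndarray:
    """Log-spaced time grid (s) with t=0 prepended.

    Spans sub-second bond dynamics up to ~230 days of IC retention.
    """
    return np.concatenate([[0.0], np.geomspace(t_min, t_max, n)])


def _rates(k_off: float, k_on: float, n_L: int, n_R: int):
    """Unbinding/rebinding rates on transient states m = 1..M."""
    M = min(n_R, n_L)
    m = np.arange(1, M + 1)
    r = m * k_off
    g = (n_R - m) * (n_L - m) * k_on
    return m, r, g


def _survival_modes(k_off: float, k_on: float, n_L: int, n_R: int):
    """Exponential-mode decomposition of single-patch survival.

    Returns ``(w, lam)`` with ``S(t) = sum_j w_j exp(lam_j t)``, or ``None``
    when the symmetrized eigenproblem is numerically unusable (very deep
    rebinding, where survival is indistinguishable from 1 on any
    representable time scale).

    The transient sub-generator on states 1..M is tridiagonal with positive
    off-diagonal products (k_on > 0), hence similar to a symmetric matrix;
    ``eigh_tridiagonal`` then gives all modes stably in O(M^2).
    """
    M = min(n_R, n_L)
    if M == 0:
        return np.array([0.0]), np.array([0.0])
    _, r, g = _rates(k_off, k_on, n_L, n_R)
    diag = -(r + g)
    if M == 1:
        return np.array([1.0]), diag.copy()
    if k_on == 0.0:
        # Independent bonds: S(t) = 1 - (1 - e^{-k_off t})^M expanded in modes.
        j = np.arange(1, M + 1)
        from scipy.special import comb

        w = -comb(M, j) * (-1.0) ** j
        return w, -j * k_off
    a = r[1:]  # gain into m from m+1 (bond opening)
    b = g[:-1]  # gain into m from m-1 (rebinding)
    lam, W = eigh_tridiagonal(diag, np.sqrt(a * b))
    # Generator eigenvalues are <= 0; clip eigensolver noise so that modes
    # never grow.
    lam = np.minimum(lam, 0.0)
    # Similarity scaling D Q D^-1 symmetric, log D_m accumulated for range.
    logD = np.concatenate([[0.0], 0.5 * np.cumsum(np.log(a) - np.log(b))])
    scale = logD[-1] - logD
    if scale.max() > 700.0:
        return None
    with np.errstate(over="ignore", invalid="ignore"):
        w = (W * np.exp(scale)[:, None]).sum(axis=0) * W[-1, :]
    s0 = w.sum()
    if not np.isfinite(s0) or abs(s0 - 1.0) > 1e-6:
        return None
    return w, lam


def solve_master_equation(
    params: BondKineticsParams, patch: PatchSpec, times: np.ndarray
) -> MasterEquationSolution:
    """Solve the one-step master equation for one patch on a time grid.

    States ``m = 0..M`` with ``M = min(n_R, n_L)``; initial mass at
    ``m = M``; ``m = 0`` absorbing.  A patch with no receptors returns the
    degenerate solution with all mass at ``m = 0`` (survival identically 0).
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size == 0:
        raise ValueError("times must be a non-empty 1-D array")
    if times[0] != 0.0 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing and start at 0")
    n_R, n_L = patch.n_R, params.n_L
    M = min(n_R, n_L)
    if M == 0:
        P = np.ones((1, times.size))
        return MasterEquationSolution(times=times, P=P, n_R=n_R, n_L=n_L)

    k_off, k_on = params.k_off, params.k_on
    if k_on == 0.0:
        # Independent-bond closed form (binomial occupation).
        e = np.exp(-k_off * times)[None, :]
        m = np.arange(M + 1)[:, None]
        from scipy.special import comb

        P = comb(M, m) * e**m * (1.0 - e) ** (M - m)
    else:
        P = _solve_transient(params, n_R, times)
    P = np.clip(P, 0.0, 1.0)
    return MasterEquationSolution(times=times, P=P, n_R=n_R, n_L=n_L)


def _solve_transient(params: BondKineticsParams, n_R: int, times: np.ndarray) -> np.ndarray:
    """Full P_m(t) via the symmetrized eigenbasis, expm fallback."""
    k_off, k_on, n_L = params.k_off, params.k_on, params.n_L
    M = min(n_R, n_L)
    _, r, g = _rates(k_off, k_on, n_L, n_R)
    diag = -(r + g)
    if M == 1:
        p = np.exp(diag[0] * times)[None, :]
        return np.vstack([1.0 - p, p])
    a, b = r[1:], g[:-1]
    lam, W = eigh_tridiagonal(diag, np.sqrt(a * b))
    lam = np.minimum(lam, 0.0)
    logD = np.concatenate([[0.0], 0.5 * np.cumsum(np.log(a) - np.log(b))])
    scale_m = logD[-1] - logD  # exponent of D_M / D_m
    ok = scale_m.max() < 700.0
    if ok:
        with np.errstate(over="ignore", invalid="ignore"):
            # p_m(t) = sum_j e^{lM-lm} W[m,j] W[M,j] e^{lam_j t}
            coeff = W * W[-1, :][None, :] * np.exp(scale_m)[:, None]
            p = coeff @ np.exp(lam[:, None] * times[None, :])
        ok = np.isfinite(p).all() and abs(p[:, 0].sum() - 1.0) < 1e-6
    if not ok:
        p = _expm_transient(diag, r, g, times)
    P0 = np.clip(1.0 - p.sum(axis=0), 0.0, 1.0)
    return np.vstack([P0, p])


def _expm_transient(diag, r, g, times):
    """Matrix-exponential fallback for regimes where the symmetrized
    eigenbasis over/underflows (extreme rebinding)."""
    M = diag.size
    Q = np.diag(diag)
    for i in range(M - 1):
        Q[i, i + 1] = r[i + 1]
        Q[i + 1, i] = g[i]
    p = np.empty((M, times.size))
    p0 = np.zeros(M)
    p0[-1] = 1.0
    for k, t in enumerate(times):
        p[:, k] = expm(Q * t) @ p0
    return p


def survival_probability(sol: MasterEquationSolution) -> SurvivalCurve:
    """Survival S(t) = P(m >= 1) = 1 - P_0(t) for one patch."""
    S = np.clip(1.0 - sol.P[0], 0.0, 1.0)
    return SurvivalCurve(times=sol.times, S=S, mean_n_R=float(sol.n_R), kind="single")


def _mixture_terms(params: BondKineticsParams, mean_n_R: float, mass_tol: float = 1e-8):
    """Poisson-weighted survival modes over the central receptor-count range.

    The returned list covers at least ``1 - mass_tol`` of the nonzero-count
    probability mass; the n_R = 0 term contributes survival 0 and is
    represented only through the missing weight.
    """
    if mean_n_R == 0.0:
        return []
    lo = max(1, int(poisson.ppf(mass_tol / 2, mean_n_R)))
    hi = int(poisson.isf(mass_tol / 2, mean_n_R))
    terms = []
    for n_R in range(lo, hi + 1):
        pw = poisson.pmf(n_R, mean_n_R)
        modes = _survival_modes(params.k_off, params.k_on, params.n_L, n_R)
        terms.append((pw, n_R, modes))
    return terms


def _mixture_S(terms, t):
    """Evaluate the Poisson-averaged survival at times t; returns 1-D."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    out = np.zeros(t.size)
    for pw, n_R, modes in terms:
        if modes is None:
            # Deep-rebinding regime: survival indistinguishable from 1.
            out += pw
        else:
            w, lam = modes
            out += pw * (np.exp(np.outer(lam, t)) * w[:, None]).sum(axis=0)
    return np.clip(out, 0.0, 1.0)


def poisson_mixture_survival(
    params: BondKineticsParams, mean_n_R: float, times: np.ndarray
) -> SurvivalCurve:
    """Mean IC survival over patches with Poisson-distributed CR2 counts.

    ``<S(t)> = sum_nR Poisson(n_R; mean) S_{n_R}(t)``; empty patches
    (n_R = 0) never hold an IC and contribute S = 0, so ``<S(0)> =
    1 - exp(-mean)``.
    """
    if mean_n_R < 0:
        raise ValueError(f"mean_n_R must be >= 0, got {mean_n_R}")
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size == 0 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be a non-empty strictly increasing 1-D array")
    terms = _mixture_terms(params, mean_n_R)
    S = _mixture_S(terms, times) if terms else np.zeros(times.size)
    return SurvivalCurve(times=times, S=S, mean_n_R=float(mean_n_R), kind="poisson")


def ic_surface_level(curve: SurvivalCurve) -> np.ndarray:
    """Mean IC surface level ``<S(t)> * <n_R>`` (ICs per patch)."""
    if curve.kind != "poisson":
        raise ValueError("ic_surface_level is defined for Poisson-averaged curves")
    return curve.S * curve.mean_n_R


def half_life(curve: SurvivalCurve) -> float:
    """First time the curve reaches half its level at the first grid point.

    Interpolates log-linearly in time between the bracketing grid points
    (linearly when the bracket starts at t = 0).  Raises
    :class:`GridTooShortError` when the level never reaches half within the
    grid.
    """
    S = curve.S
    if S[0] <= 0:
        raise ValueError("initial level must be > 0")
    target = 0.5 * S[0]
    below = np.nonzero(S <= target)[0]
    if below.size == 0:
        raise GridTooShortError(
            f"level never reached half of {S[0]:.4g} within the grid "
            f"(final level {S[-1]:.4g}); extend the time grid"
        )
    i = below[0]
    if i == 0:
        return float(curve.times[0])
    t0, t1 = curve.times[i - 1], curve.times[i]
    s0, s1 = S[i - 1], S[i]
    if s0 == s1:
        return float(t1)
    frac = (s0 - target) / (s0 - s1)
    if t0 <= 0:
        return float(t0 + frac * (t1 - t0))
    return float(np.exp(np.log(t0) + frac * (np.log(t1) - np.log(t0))))


def mixture_level_at(params: BondKineticsParams, mean_n_R: float, t) -> np.ndarray:
    """Poisson-averaged IC surface level ``<S(t)> * <n_R>`` at arbitrary times."""
    terms = _mixture_terms(params, mean_n_R)
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if not terms:
        return np.zeros(t.size)
    return _mixture_S(terms, t) * mean_n_R


def mixture_half_life(
    params: BondKineticsParams, mean_n_R: float, t_max: float = 1e16
) -> float:
    """Half-life of the Poisson-averaged IC level, solved continuously.

    Uses the exponential-mode representation directly (no grid), bracketing
    the crossing on log-time.  Returns ``inf`` when the level has not halved
    by ``t_max`` (effectively irreversible retention).
    """
    terms = _mixture_terms(params, mean_n_R)
    if not terms:
        raise ValueError("mean_n_R = 0: no ICs are ever loaded")
    s0 = float(_mixture_S(terms, 0.0)[0])

    def f(logt):
        return float(_mixture_S(terms, math.exp(logt))[0]) - 0.5 * s0

    lo, hi = math.log(1e-6), math.log(t_max)
    if f(hi) > 0:
        return math.inf
    if f(lo) <= 0:
        return 0.0
    return math.exp(brentq(f, lo, hi, xtol=1e-9))


def density_to_mean_nR(density: float, patch_area: float) -> float:
    """Convert a CR2 surface density (molecules/um^2) to a mean per-patch count."""
    if density < 0:
        raise ValueError(f"density must be >= 0, got {density}")
    if patch_area <= 0:
        raise ValueError(f"patch_area must be > 0, got {patch_area}")
    return density * patch_area


@dataclass(frozen=True)
class CalibrationResult:
    """Outcome of :func:`calibrate_rebinding`.

    ``residuals`` holds the relative half-life error at every anchor under
    the selected parameters; ``fitted_half_lives`` the model half-lives (s).
    """

    params: BondKineticsParams
    residuals: np.ndarray
    fitted_half_lives: np.ndarray
    anchor_densities: np.ndarray
    anchor_half_lives: np.ndarray


def calibrate_rebinding(
    anchor_densities,
    anchor_half_lives,
    k_off: float,
    n_L_range=(2, 128),
    k_on_range=(1e-10, 1e6),
    patch_area: float = DEFAULT_PATCH_AREA_UM2,
    anchor_rtol: float = 0.05,
) -> CalibrationResult:
    """Fit the rebinding rate (and IC valency) to measured half-life anchors.

    For each candidate ``n_L`` the half-life at the first anchor density is
    matched exactly by a monotone root find on ``log k_on`` (half-life is
    strictly increasing in ``k_on``); the ``(n_L, k_on)`` pair minimizing the
    maximum relative residual over the remaining anchors is selected, ties
    broken toward the smallest ``n_L``.

    Raises :class:`InfeasibleAnchorsError` when the anchors are not
    monotone (half-life decreasing with density) and
    :class:`CalibrationError` when no candidate reproduces the first anchor
    within ``anchor_rtol``.
    """
    dens = np.asarray(anchor_densities, dtype=float)
    hl = np.asarray(anchor_half_lives, dtype=float)
    if dens.size < 1 or dens.size != hl.size:
        raise ValueError("need >= 1 anchor with matching densities and half-lives")
    if np.any(np.diff(dens) <= 0):
        raise ValueError("anchors must be sorted by strictly increasing density")
    if np.any(hl <= 0):
        raise ValueError("anchor half-lives must be > 0")
    if np.any(np.diff(hl) < 0):
        raise InfeasibleAnchorsError(
            "anchor half-lives decrease with density; the model's half-life "
            "is non-decreasing in receptor density, so no parameters exist"
        )

    means = dens * patch_area
    target1 = hl[0]
    log_lo, log_hi = math.log(k_on_range[0]), math.log(k_on_range[1])
    best = None  # (max_residual, n_L, k_on, fitted)

    for n_L in range(int(n_L_range[0]), int(n_L_range[1]) + 1):
        params0 = BondKineticsParams(k_off=k_off, k_on=0.0, n_L=n_L, patch_area=patch_area)

        def mismatch(log_kon):
            p = replace(params0, k_on=math.exp(log_kon))
            h = mixture_half_life(p, means[0])
            return math.log(h / target1) if math.isfinite(h) else 50.0

        try:
            f_lo, f_hi = mismatch(log_lo), mismatch(log_hi)
        except (ValueError, GridTooShortError):
            continue
        if f_lo > 0 or f_hi < 0 or not (np.isfinite(f_lo) and np.isfinite(f_hi)):
            continue  # first anchor unreachable for this valency
        log_kon = brentq(mismatch, log_lo, log_hi, xtol=1e-4)
        k_on = math.exp(log_kon)
        p = replace(params0, k_on=k_on)
        fitted = np.array([mixture_half_life(p, m) for m in means])
        res = np.abs(fitted - hl) / hl
        score = res[1:].max() if res.size > 1 else res[0]
        if best is None or score < best[0] - 1e-12:
            best = (score, n_L, k_on, fitted)

    if best is None:
        raise CalibrationError(
            "no candidate n_L could reproduce the first anchor half-life "
            f"within k_on range {k_on_range}"
        )
    score, n_L, k_on, fitted = best
    res = np.abs(fitted - hl) / hl
    if res[0] > anchor_rtol:
        raise CalibrationError(
            f"first anchor reproduced only to {res[0]:.1%} (> {anchor_rtol:.0%})",
            best_residual=float(res[0]),
        )
    params = BondKineticsParams(k_off=k_off, k_on=k_on, n_L=n_L, patch_area=patch_area)
    return CalibrationResult(
        params=params,
        residuals=res,
        fitted_half_lives=fitted,
        anchor_densities=dens,
        anchor_half_lives=hl,
    )
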