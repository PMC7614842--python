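"""Measurement-side fits: BLI kinetics, bead calibration, decay, ELISA titer.

The CR2-C3dg interaction is characterized by biolayer interferometry (BLI):
sensorgrams (response in RU versus time) recorded over an analyte
concentration series are fitted globally with a 1:1 Langmuir model, and the
equilibrium plateau responses with the binding hyperbola
``R_eq(C) = R_max C / (C + K_D)``.  Quantitative flow cytometry converts
CR2 staining MFI to absolute receptor densities through a fluorescent-bead
calibration line, and in-vivo antigen decay observations are summarized by a
single-exponential fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import lmfit
import numpy as np
from scipy import stats

from .errors import FitError

__all__ = [
    "Sensorgram",
    "KineticFit",
    "EquilibriumFit",
    "BeadCalibration",
    "DecayFit",
    "simulate_sensorgram",
    "fit_kinetic",
    "fit_equilibrium",
    "bead_calibration",
    "mfi_to_density",
    "fit_decay",
    "elisa_titer",
]


@dataclass(frozen=True)
class Sensorgram:
    """One BLI trace: association up to ``association_end_time``, then
    dissociation."""

    analyte_concentration: float  # M
    times: np.ndarray  # s
    response: np.ndarray  # RU
    association_end_time: float  # s

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValueError("sensorgram times must be strictly increasing")
        if not np.all(np.isfinite(self.response)):
            raise ValueError("sensorgram responses must be finite")
        if not (t[0] <= self.association_end_time <= t[-1]):
            raise ValueError("association_end_time outside the time range")


@dataclass(frozen=True)
class KineticFit:
    k_on: float  # M^-1 s^-1
    k_off: float  # s^-1
    R_max: float  # RU
    residual: float  # sum of squares

    @property
    def K_D(self) -> float:
        return self.k_off / self.k_on


@dataclass(frozen=True)
class EquilibriumFit:
    K_D: float  # M
    R_max: float  # RU
    residual: float


@dataclass(frozen=True)
class BeadCalibration:
    """Least-squares line mapping fluorescence (MFI) to molecule count."""

    slope: float
    intercept: float
    r_squared: float


@dataclass(frozen=True)
class DecayFit:
    initial_level: float  # MFI units at day 0
    rate: float  # day^-1
    residual: float

    @property
    def half_life_days(self) -> float:
        return np.log(2) / self.rate


def _langmuir_response(t, t_assoc, k_on, k_off, R_max, conc):
    """Piecewise 1:1 Langmuir response (association then dissociation)."""
    K_D = k_off / k_on
    R_eq = R_max * conc / (conc + K_D)
    k_obs = k_on * conc + k_off
    assoc = R_eq * (1.0 - np.exp(-k_obs * np.minimum(t, t_assoc)))
    r_end = R_eq * (1.0 - np.exp(-k_obs * t_assoc))
    dissoc = r_end * np.exp(-k_off * np.maximum(t - t_assoc, 0.0))
    return np.where(t <= t_assoc, assoc, dissoc)


def simulate_sensorgram(
    k_on: float,
    k_off: float,
    R_max: float,
    concentration: float,
    t_assoc: float,
    t_dissoc: float,
    noise_sd: float = 0.0,
    seed: int = 0,
    dt: float = 0.5,
) -> Sensorgram:
    """Generate a 1:1 Langmuir sensorgram, optionally with Gaussian noise."""
    if k_on <= 0 or k_off <= 0:
        raise ValueError("k_on and k_off must be > 0")
    if t_assoc <= 0 or t_dissoc <= 0:
        raise ValueError("phase durations must be > 0")
    times = np.arange(0.0, t_assoc + t_dissoc + dt / 2, dt)
    resp = _langmuir_response(times, t_assoc, k_on, k_off, R_max, concentration)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        resp = resp + rng.normal(0.0, noise_sd, size=resp.shape)
    return Sensorgram(
        analyte_concentration=float(concentration),
        times=times,
        response=resp,
        association_end_time=float(t_assoc),
    )


def fit_kinetic(sensorgrams) -> KineticFit:
    """Global 1:1 kinetic fit with k_on, k_off, R_max shared across traces.

    Initial guesses come from a coarse log-spaced grid search; refinement is
    Levenberg-Marquardt least squares over all traces simultaneously.
    """
    sgs = list(sensorgrams)
    if len(sgs) == 0:
        raise ValueError("need at least one sensorgram")
    if len(sgs) < 2:
        import warnings

        warnings.warn(
            "single-concentration kinetic fits are ill-conditioned", stacklevel=2
        )

    r_top = max(float(np.max(s.response)) for s in sgs)

    def residual_vec(log_kon, log_koff, R_max):
        parts = [
            s.response
            - _langmuir_response(
                s.times,
                s.association_end_time,
                10.0**log_kon,
                10.0**log_koff,
                R_max,
                s.analyte_concentration,
            )
            for s in sgs
        ]
        return np.concatenate(parts)

    # coarse grid for initial guesses
    best = None
    for lk in np.linspace(3.0, 8.0, 11):
        for lf in np.linspace(-4.0, 1.0, 11):
            ss = float(np.sum(residual_vec(lk, lf, r_top) ** 2))
            if best is None or ss < best[0]:
                best = (ss, lk, lf)
    _, lk0, lf0 = best

    p = lmfit.Parameters()
    p.add("log_kon", value=lk0, min=0.0, max=12.0)
    p.add("log_koff", value=lf0, min=-8.0, max=3.0)
    p.add("R_max", value=r_top, min=1e-12)
    out = lmfit.minimize(
        lambda pars: residual_vec(
            pars["log_kon"].value, pars["log_koff"].value, pars["R_max"].value
        ),
        p,
    )
    if not out.success:
        raise FitError(f"kinetic fit did not converge: {out.message}")
    return KineticFit(
        k_on=10.0 ** out.params["log_kon"].value,
        k_off=10.0 ** out.params["log_koff"].value,
        R_max=out.params["R_max"].value,
        residual=float(np.sum(out.residual**2)),
    )


def fit_equilibrium(concentrations, plateau_responses) -> EquilibriumFit:
    """Least-squares fit of the binding hyperbola to plateau responses."""
    conc = np.asarray(concentrations, dtype=float)
    resp = np.asarray(plateau_responses, dtype=float)
    if conc.size < 3:
        raise ValueError("need >= 3 concentration points")
    if np.ptp(resp) == 0:
        raise FitError("all plateau responses identical: degenerate fit")

    p = lmfit.Parameters()
    p.add("K_D", value=float(np.median(conc)), min=1e-15)
    p.add("R_max", value=float(resp.max()), min=1e-12)
    out = lmfit.minimize(
        lambda pars: resp
        - pars["R_max"].value * conc / (conc + pars["K_D"].value),
        p,
    )
    if not out.success:
        raise FitError(f"equilibrium fit did not converge: {out.message}")
    return EquilibriumFit(
        K_D=out.params["K_D"].value,
        R_max=out.params["R_max"].value,
        residual=float(np.sum(out.residual**2)),
    )


def bead_calibration(bead_mfi, bead_molecule_counts) -> BeadCalibration:
    """Ordinary least-squares line through the bead panel (MFI -> molecules).

    The intercept is retained to absorb autofluorescence background.
    """
    mfi = np.asarray(bead_mfi, dtype=float)
    cnt = np.asarray(bead_molecule_counts, dtype=float)
    if mfi.size < 2 or mfi.size != cnt.size:
        raise ValueError("need >= 2 matched bead levels")
    if np.ptp(mfi) == 0:
        raise FitError("all bead MFIs identical: degenerate panel")
    res = stats.linregress(mfi, cnt)
    return BeadCalibration(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )


def mfi_to_density(mfi: float, calibration: BeadCalibration, cell_surface_area: float) -> float:
    """Convert a cell's MFI to a receptor surface density (molecules/um^2).

    The per-cell molecule count is floored at zero before dividing by the
    cell surface area.
    """
    if cell_surface_area <= 0:
        raise ValueError("cell_surface_area must be > 0")
    molecules = max(0.0, calibration.slope * mfi + calibration.intercept)
    return molecules / cell_surface_area


def fit_decay(days, levels) -> DecayFit:
    """Single-exponential fit ``A exp(-rate * day)`` to antigen-level decay."""
    d = np.asarray(days, dtype=float)
    y = np.asarray(levels, dtype=float)
    if d.size < 3:
        raise ValueError("need >= 3 time points")
    if np.all(y <= 0):
        raise FitError("all levels non-positive: nothing to fit")

    # log-linear regression on the positive points for initial guesses
    pos = y > 0
    lr = stats.linregress(d[pos], np.log(y[pos]))
    p = lmfit.Parameters()
    p.add("A", value=float(np.exp(lr.intercept)), min=1e-300)
    p.add("rate", value=float(max(-lr.slope, 1e-6)), min=1e-9)
    out = lmfit.minimize(
        lambda pars: y - pars["A"].value * np.exp(-pars["rate"].value * d), p
    )
    if not out.success:
        raise FitError(f"decay fit did not converge: {out.message}")
    return DecayFit(
        initial_level=out.params["A"].value,
        rate=out.params["rate"].value,
        residual=float(np.sum(out.residual**2)),
    )


def elisa_titer(dilution: float) -> float:
    """Antibody titer from an endpoint dilution: ``-log2(dilution) * 40``."""
    if not 0 < dilution <= 1:
        raise ValueError(f"dilution must be in (0, 1], got {dilution}")
    return -np.log2(dilution) * 40.0
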