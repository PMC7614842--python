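"""Master-equation solver, Poisson averaging, half-life and calibration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fdcret as f
from fdcret.bond_kinetics import _survival_modes

from oracles import rk4_survival


@pytest.mark.parametrize(
    "m, n_R, n_L, expected",
    [
        (0, 250, 40, 250 * 40),
        (40, 250, 40, 0),
        (2, 5, 2, 0),
        (1, 3, 2, 2),
        (3, 7, 5, 8),
    ],
)
def test_configuration_count(m, n_R, n_L, expected):
    assert f.configuration_count(m, n_R, n_L) == expected


@pytest.mark.parametrize("m, n_R, n_L", [(-1, 3, 3), (4, 5, 3), (6, 3, 8)])
def test_configuration_count_domain(m, n_R, n_L):
    with pytest.raises(ValueError):
        f.configuration_count(m, n_R, n_L)


def test_single_ligand_is_pure_exponential():
    """With n_L = 1 rebinding is impossible (C(1) = 0): S(t) = e^{-k_off t}."""
    p = f.BondKineticsParams(k_off=0.15, k_on=3.0, n_L=1)
    times = f.default_time_grid(t_max=1e3, n=50)
    sol = f.solve_master_equation(p, f.PatchSpec(7), times)
    S = f.survival_probability(sol).S
    assert np.max(np.abs(S - np.exp(-0.15 * times))) < 1e-6
    # half-life of the pure exponential (dense grid around the crossing)
    tt = f.default_time_grid(t_min=1.0, t_max=10.0, n=200)
    curve = f.SurvivalCurve(times=tt, S=np.exp(-0.15 * tt), mean_n_R=1.0)
    assert f.half_life(curve) == pytest.approx(np.log(2) / 0.15, rel=1e-4)


def test_independent_bonds_closed_form():
    """k_on = 0: bonds decay independently, S = 1 - (1 - e^{-k_off t})^M."""
    times = f.default_time_grid(t_max=100.0, n=60)
    for n_R, n_L in [(2, 2), (5, 3), (3, 8)]:
        M = min(n_R, n_L)
        p = f.BondKineticsParams(k_off=1.0, k_on=0.0, n_L=n_L)
        S = f.survival_probability(
            f.solve_master_equation(p, f.PatchSpec(n_R), times)
        ).S
        expected = 1.0 - (1.0 - np.exp(-times)) ** M
        assert np.max(np.abs(S - expected)) < 1e-6


def test_master_equation_against_fixed_step_oracle():
    """Eigendecomposition route agrees with brute-force RK4 integration."""
    # frozen value computed with the RK4 oracle at dt = 1e-4
    p = f.BondKineticsParams(k_off=1.0, k_on=1.0, n_L=2)
    sol = f.solve_master_equation(p, f.PatchSpec(2), np.array([0.0, 1.0]))
    S1 = f.survival_probability(sol).S[-1]
    assert S1 == pytest.approx(0.6651433193661926, abs=1e-9)
    # live cross-checks at coarser oracle resolution
    for k_off, k_on, n_R, n_L, t in [(0.5, 2.0, 4, 3, 0.7), (2.0, 0.3, 3, 5, 1.3)]:
        pp = f.BondKineticsParams(k_off=k_off, k_on=k_on, n_L=n_L)
        sol = f.solve_master_equation(pp, f.PatchSpec(n_R), np.array([0.0, t]))
        assert f.survival_probability(sol).S[-1] == pytest.approx(
            rk4_survival(k_off, k_on, n_R, n_L, t, dt=1e-3), abs=1e-6
        )


def test_zero_receptors_degenerate():
    p = f.BondKineticsParams(k_off=0.15, k_on=1.0, n_L=4)
    sol = f.solve_master_equation(p, f.PatchSpec(0), np.array([0.0, 1.0, 10.0]))
    assert np.all(f.survival_probability(sol).S == 0.0)


@settings(max_examples=30, derandomize=True, deadline=None)
@given(
    k_off=st.floats(0.01, 10.0),
    k_on=st.floats(0.0, 5.0),
    n_R=st.integers(1, 40),
    n_L=st.integers(1, 12),
)
def test_probability_conservation_and_shape(k_off, k_on, n_R, n_L):
    """Columns stochastic to 1e-8, entries in [0,1], initial mass at m = M,
    survival non-increasing."""
    p = f.BondKineticsParams(k_off=k_off, k_on=k_on, n_L=n_L)
    times = f.default_time_grid(t_min=0.01, t_max=1e4, n=40)
    sol = f.solve_master_equation(p, f.PatchSpec(n_R), times)
    assert np.max(np.abs(sol.P.sum(axis=0) - 1.0)) < 1e-8
    assert sol.P.min() >= 0.0 and sol.P.max() <= 1.0 + 1e-12
    assert sol.P[min(n_R, n_L), 0] == pytest.approx(1.0, abs=1e-12)
    S = f.survival_probability(sol).S
    assert np.all(np.diff(S) <= 1e-9)


def test_survival_eventually_vanishes():
    """All bonds eventually break: S decays to ~0 beyond the slowest mode."""
    p = f.BondKineticsParams(k_off=0.5, k_on=0.8, n_L=3)
    w, lam = _survival_modes(0.5, 0.8, 3, 6)
    t_late = 40.0 / abs(lam.max())  # slowest relaxation time x 40
    sol = f.solve_master_equation(
        p, f.PatchSpec(6), np.array([0.0, 1.0, t_late])
    )
    assert f.survival_probability(sol).S[-1] < 1e-10


def test_poisson_mixture_trivials_and_oracle():
    times = np.array([0.0, 1.0, 2.0])
    # mean 0: no receptors anywhere
    p = f.BondKineticsParams(k_off=1.0, k_on=0.5, n_L=3)
    assert np.all(f.poisson_mixture_survival(p, 0.0, times).S == 0.0)
    # n_L = 1: only empty patches never load; the rest decay exponentially
    p1 = f.BondKineticsParams(k_off=0.15, k_on=2.0, n_L=1)
    mean = 3.0
    S = f.poisson_mixture_survival(p1, mean, times).S
    expected = (1.0 - np.exp(-mean)) * np.exp(-0.15 * times)
    assert np.max(np.abs(S - expected)) < 1e-7
    # frozen truncated-sum RK4 oracle value (mean 5, n_L 3, k_off 1, k_on 0.5)
    S2 = f.poisson_mixture_survival(p, 5.0, times).S[-1]
    assert S2 == pytest.approx(0.6624328575167937, abs=1e-6)
    assert f.mixture_level_at(p, 5.0, 2.0)[0] == pytest.approx(
        5.0 * 0.6624328575167937, abs=1e-5
    )


def test_ic_surface_level_contract_and_loading():
    times = np.array([0.0, 1.0])
    p = f.BondKineticsParams(k_off=0.15, k_on=0.0, n_L=1)
    curve = f.poisson_mixture_survival(p, 250.0, times)
    level0 = f.ic_surface_level(curve)[0]
    assert level0 == pytest.approx(250.0 * (1 - np.exp(-250.0)), rel=1e-6)
    # initial loading proportional to mean receptor count
    c2 = f.poisson_mixture_survival(p, 500.0, times)
    assert f.ic_surface_level(c2)[0] / level0 == pytest.approx(2.0, rel=1e-6)
    # level is only defined for Poisson-averaged curves
    single = f.survival_probability(
        f.solve_master_equation(p, f.PatchSpec(3), times)
    )
    with pytest.raises(ValueError):
        f.ic_surface_level(single)


def test_half_life_interpolation_and_grid_error():
    times = f.default_time_grid(t_min=0.01, t_max=50.0, n=200)
    # two independent bonds: t_1/2 solves (1 - e^{-t})^2 = 1/2
    S = 1.0 - (1.0 - np.exp(-times)) ** 2
    curve = f.SurvivalCurve(times=times, S=S, mean_n_R=2.0)
    assert f.half_life(curve) == pytest.approx(1.2279471772995159, rel=1e-4)
    short = f.SurvivalCurve(times=times[:5], S=S[:5], mean_n_R=2.0)
    with pytest.raises(f.GridTooShortError):
        f.half_life(short)


@pytest.mark.parametrize(
    "density, area, expected", [(250.0, 1.0, 250.0), (250.0, 0.5, 125.0), (0.0, 2.0, 0.0)]
)
def test_density_to_mean_nR(density, area, expected):
    assert f.density_to_mean_nR(density, area) == expected


def test_density_to_mean_nR_domain():
    with pytest.raises(ValueError):
        f.density_to_mean_nR(-1.0, 1.0)
    with pytest.raises(ValueError):
        f.density_to_mean_nR(1.0, 0.0)


def test_half_life_monotone_in_density_valency_rebinding():
    base = dict(k_off=0.15, k_on=0.3, n_L=4)
    hl_d = [
        f.mixture_half_life(f.BondKineticsParams(**base), m) for m in (2.0, 4.0, 6.0)
    ]
    assert np.all(np.diff(hl_d) >= 0)
    hl_v = [
        f.mixture_half_life(f.BondKineticsParams(k_off=0.15, k_on=0.3, n_L=n), 4.0)
        for n in (2, 4, 6)
    ]
    assert np.all(np.diff(hl_v) >= 0)
    hl_k = [
        f.mixture_half_life(f.BondKineticsParams(k_off=0.15, k_on=k, n_L=4), 4.0)
        for k in (0.1, 0.3, 0.9)
    ]
    assert np.all(np.diff(hl_k) >= 0)


def test_calibration_round_trip_recovers_truth():
    """Anchors generated by the forward model pin down (n_L, k_on)."""
    truth = f.BondKineticsParams(k_off=0.15, k_on=0.45, n_L=6)
    dens = (250.0, 375.0)
    hls = [
        f.mixture_half_life(truth, f.density_to_mean_nR(d, truth.patch_area))
        for d in dens
    ]
    res = f.calibrate_rebinding(dens, hls, k_off=0.15, n_L_range=(2, 12))
    assert res.params.n_L == truth.n_L
    assert res.params.k_on == pytest.approx(truth.k_on, rel=0.01)


def test_calibration_single_anchor_fixed_valency():
    truth = f.BondKineticsParams(k_off=0.15, k_on=0.45, n_L=6)
    hl = f.mixture_half_life(truth, f.density_to_mean_nR(250.0, truth.patch_area))
    res = f.calibrate_rebinding([250.0], [hl], k_off=0.15, n_L_range=(6, 6))
    assert res.params.k_on == pytest.approx(truth.k_on, rel=0.01)


def test_calibration_rejects_nonmonotone_anchors():
    with pytest.raises(f.InfeasibleAnchorsError):
        f.calibrate_rebinding(
            [250.0, 375.0], [10 * 3600.0, 1 * 3600.0], k_off=0.15
        )


def test_params_validation():
    with pytest.raises(ValueError):
        f.BondKineticsParams(k_off=0.0, k_on=1.0, n_L=2)
    with pytest.raises(ValueError):
        f.BondKineticsParams(k_off=1.0, k_on=-0.1, n_L=2)
    with pytest.raises(ValueError):
        f.BondKineticsParams(k_off=1.0, k_on=1.0, n_L=0)
    with pytest.raises(ValueError):
        f.PatchSpec(-1)
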