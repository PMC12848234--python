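"""Optimality model: closed form vs brute force, chi bounds, limits."""

import numpy as np
import pytest

from photocap.kinetics import entropy_term, temperature_scalar
from photocap.optimality import (
    DEFAULT_CONSTANTS,
    CostConstant,
    CostInfeasibleError,
    OptimalityEnv,
    atmospheric_pressure,
    light_limited_net_gain,
    optimal_chi,
    optimal_vcmax,
    photosynthesis_coefficients,
    predict_vcmax25_optimality,
)


def test_sea_level_pressure_and_monotonicity():
    assert atmospheric_pressure(0.0) == pytest.approx(101_325.0)
    z = np.linspace(0, 4000, 9)
    p = atmospheric_pressure(z)
    assert np.all(np.diff(p) < 0)


def test_pressure_matches_independent_barometric_evaluation():
    # independent hand evaluation of the standard-atmosphere formula at 2500 m
    expected = 101_325.0 * (1 - 0.0065 * 2500 / 288.15) ** (
        9.80665 * 0.028963 / (8.314 * 0.0065)
    )
    assert atmospheric_pressure(2500.0) == pytest.approx(expected, abs=1.0)


def test_pressure_domain_guard():
    with pytest.raises(ValueError):
        atmospheric_pressure(9500.0)


def test_coefficients_reference_values_and_trends():
    g25, K25, eta25 = photosynthesis_coefficients(25.0, 101_325.0)
    assert eta25 == pytest.approx(1.0, abs=1e-12)
    # at the 25 degC reference the Arrhenius factors are exactly 1
    kc, ko = 41.03, 28_210.0
    expected_K = kc * (1 + 0.2095 * 101_325.0 / ko)
    assert g25 == pytest.approx(4.332, rel=1e-6)
    assert K25 == pytest.approx(expected_K, rel=1e-6)
    g35, K35, _ = photosynthesis_coefficients(35.0, 101_325.0)
    assert g35 > g25 and K35 > K25


def test_chi_limits_in_vpd():
    """chi -> gammastar/ca as D -> inf; chi -> 1 as D -> 0; chi decreases in D."""
    base = dict(t_g=25.0, par=800.0, ca=400.0, elevation=0.0)
    _, g, _, _, _, chi_hi, _, _, _ = optimal_chi(OptimalityEnv(vpd=50.0, **base))
    _, _, _, _, _, chi_lo, _, _, _ = optimal_chi(OptimalityEnv(vpd=0.0, **base))
    ca_pa = 400e-6 * 101_325.0
    assert chi_hi < 0.45 and chi_hi > g / ca_pa
    assert chi_lo > 0.97
    chis = [
        optimal_chi(OptimalityEnv(vpd=d, **base))[5] for d in (0.5, 1.0, 2.0)
    ]
    assert chis[0] > chis[1] > chis[2]


def test_chi_bounds_over_environment_grid():
    tg, vpd, ca, z = np.meshgrid(
        [5.0, 15.0, 25.0], [0.3, 1.0, 3.0], [360.0, 400.0], [0.0, 2000.0]
    )
    env = OptimalityEnv(
        t_g=tg.ravel(), par=800.0, vpd=vpd.ravel(), ca=ca.ravel(), elevation=z.ravel()
    )
    ints = optimal_vcmax(env)
    lower = ints.gammastar / (env.ca * 1e-6 * ints.pressure)
    assert np.all(ints.chi >= lower) and np.all(ints.chi <= 1.0)
    assert np.all((ints.m > 0) & (ints.m < 1) & (ints.mc > 0) & (ints.mc < 1))


def test_closed_form_matches_bruteforce_gridsearch(rng):
    """For 100 random environments the closed-form Vcmax agrees with direct
    numeric maximisation of the net-gain objective over a Jmax grid."""
    n = 100
    env = OptimalityEnv(
        t_g=rng.uniform(2, 30, n),
        par=rng.uniform(200, 2000, n),
        vpd=rng.uniform(0.2, 3.5, n),
        ca=rng.uniform(360, 420, n),
        elevation=rng.uniform(0, 3500, n),
    )
    ints = optimal_vcmax(env, CostConstant(0.053))
    theta, phi0 = DEFAULT_CONSTANTS.theta, DEFAULT_CONSTANTS.phi0
    for i in range(n):
        phi0_I = phi0 * env.par[i]
        grid = np.linspace(1e-3, 12.0 * phi0_I, 200_001)
        obj = light_limited_net_gain(grid, ints.m[i], phi0_I, 0.053, theta)
        jstar = grid[np.argmax(obj)]
        s = phi0_I + jstar
        J = (s - np.sqrt(s * s - 4 * theta * phi0_I * jstar)) / (2 * theta)
        vc_grid = ints.m[i] * J / 4.0 / ints.mc[i]
        assert vc_grid == pytest.approx(ints.vcmax[i], rel=1e-3)


def test_vcmax_linear_in_par_and_zero_at_dark():
    base = dict(t_g=20.0, vpd=1.0, ca=400.0, elevation=500.0)
    v1 = optimal_vcmax(OptimalityEnv(par=600.0, **base)).vcmax
    v2 = optimal_vcmax(OptimalityEnv(par=1200.0, **base)).vcmax
    assert v2 == pytest.approx(2.0 * v1, rel=1e-12)
    assert optimal_vcmax(OptimalityEnv(par=0.0, **base)).vcmax == pytest.approx(0.0)
    assert optimal_vcmax(OptimalityEnv(par=0.0, **base)).jmax == pytest.approx(0.0)


def test_vcmax_increases_with_vpd():
    """Stomatal closure under dry air is compensated by more carboxylation."""
    base = dict(t_g=20.0, par=800.0, ca=400.0, elevation=0.0)
    v = [optimal_vcmax(OptimalityEnv(vpd=d, **base)).vcmax for d in (0.5, 1.0, 2.0)]
    assert v[0] < v[1] < v[2]


def test_infeasible_cost_raises_typed_error():
    env = OptimalityEnv(t_g=20.0, par=800.0, vpd=1.0, ca=400.0, elevation=0.0)
    with pytest.raises(CostInfeasibleError):
        optimal_vcmax(env, CostConstant(0.5))


def test_vcmax25_conversion_identity_and_cold_site():
    env25 = OptimalityEnv(t_g=25.0, par=800.0, vpd=1.0, ca=400.0, elevation=0.0)
    vc25, ints = predict_vcmax25_optimality(env25)
    assert vc25 == pytest.approx(float(ints.vcmax), rel=1e-12)
    env_cold = OptimalityEnv(t_g=5.0, par=800.0, vpd=1.0, ca=400.0, elevation=0.0)
    vc25_cold, ints_cold = predict_vcmax25_optimality(env_cold)
    # f(5, 25) > 1 (oracle check via the kinetics scalar itself)
    f = temperature_scalar(5.0, 25.0, entropy_term(5.0))
    assert f > 1.0
    assert vc25_cold > float(ints_cold.vcmax)
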