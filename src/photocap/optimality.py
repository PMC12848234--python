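"""Eco-evolutionary optimality model of leaf photosynthetic capacity.

Two nested optimisations predict the maximum carboxylation rate at
growing-season temperature from five aboveground drivers (growing-season
temperature, PAR, VPD, ambient CO2 and elevation):

1. *Least-cost* ratio of internal to ambient CO2 (chi): the plant balances
   the unit costs of transpiration and carboxylation, giving
   chi = gammastar/ca + (1 - gammastar/ca) * xi / (xi + sqrt(D)) with
   xi = sqrt(beta (K + gammastar) / (1.6 eta*)).
2. *Coordination* of electron transport and carboxylation: Jmax is chosen
   to maximise light-limited assimilation minus a linear cost c * Jmax,
   where c is the total unit carbon cost of building and maintaining the
   photosynthetic machinery.  The closed-form solution is expressed
   through the dimensionless terms omega and omega*:

       omega  = -(1 - 2 theta) + sqrt((1 - theta) (1/(g (1 - theta g)) - 4 theta)),
                g = 4 c / m
       omega* = 1 + omega - sqrt((1 + omega)^2 - 4 theta omega)
       Jmax   = phi0 * I * omega
       Vcmax  = phi0 * I * (m / mc) * omega* / (8 theta)

Vcmax is exactly linear in absorbed light I.  All functions are
vectorised over numpy arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .kinetics import KineticsParams, DEFAULT_PARAMS, convert_vcmax

__all__ = [
    "OptimalityConstants",
    "OptimalityEnv",
    "OptimalityInternals",
    "CostConstant",
    "CostInfeasibleError",
    "DegenerateEnvironmentError",
    "atmospheric_pressure",
    "photosynthesis_coefficients",
    "optimal_chi",
    "optimal_vcmax",
    "predict_vcmax25_optimality",
    "omega_from_cost",
    "vcmax_from_omega",
]

KELVIN = 273.15
T25 = 25.0 + KELVIN
P0 = 101_325.0  # standard sea-level pressure, Pa
RGAS = 8.314


class CostInfeasibleError(ValueError):
    """The unit cost c admits no real, positive optimum (omega complex)."""


class DegenerateEnvironmentError(ValueError):
    """Internal CO2 at or below the compensation point: assimilation impossible."""


@dataclass(frozen=True)
class OptimalityConstants:
    """Biochemical constants of the optimality formulation (config-exposed).

    Defaults follow the published global-Vcmax optimality formulation:
    25-degC base rates with Arrhenius activation energies for the
    photorespiratory compensation point (gammastar) and the Michaelis
    constants of carboxylation/oxygenation, an O2 mole fraction scaled by
    atmospheric pressure, the unit-cost ratio beta of the least-cost
    criterion, light-response curvature theta and intrinsic quantum yield
    phi0.
    """

    gammastar25: float = 4.332  # Pa at standard pressure
    dha_gammastar: float = 37_830.0  # J mol-1
    kc25: float = 41.03  # Pa
    dha_kc: float = 79_430.0
    ko25: float = 28_210.0  # Pa
    dha_ko: float = 36_380.0
    o2_mole_frac: float = 0.2095
    beta_costratio: float = 146.0
    theta: float = 0.85
    phi0: float = 0.257 / 4.0  # mol mol-1
    vpd_floor_pa: float = 1.0  # avoids the chi -> 1 singularity at D = 0


DEFAULT_CONSTANTS = OptimalityConstants()


@dataclass(frozen=True)
class CostConstant:
    """Globally constant total unit carbon cost of photosynthetic machinery."""

    c: float = 0.053

    def __post_init__(self) -> None:
        if self.c <= 0:
            raise ValueError("cost must be positive")


@dataclass
class OptimalityEnv:
    """Aboveground drivers: temperature (degC), PAR (umol m-2 s-1),
    VPD (kPa), ambient CO2 (ppm) and elevation (m)."""

    t_g: np.ndarray | float
    par: np.ndarray | float
    vpd: np.ndarray | float
    ca: np.ndarray | float
    elevation: np.ndarray | float = 0.0

    def __post_init__(self) -> None:
        for name in ("t_g", "par", "vpd", "ca", "elevation"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.any(self.par < 0) or np.any(self.vpd < 0) or np.any(self.ca <= 0):
            raise ValueError("require par >= 0, vpd >= 0, ca > 0")


@dataclass
class OptimalityInternals:
    """Every derived quantity of the two optimisations (vector-valued)."""

    pressure: np.ndarray
    gammastar: np.ndarray
    K: np.ndarray
    eta_star: np.ndarray
    xi: np.ndarray
    chi: np.ndarray
    ci: np.ndarray
    m: np.ndarray
    mc: np.ndarray
    omega: np.ndarray
    omega_star: np.ndarray
    theta: float
    phi0: float
    beta_costratio: float
    jmax: np.ndarray
    vcmax: np.ndarray

    def as_dict(self):
        return asdict(self)


def atmospheric_pressure(elevation):
    """Atmospheric pressure (Pa) from elevation (m), standard atmosphere."""
    z = np.asarray(elevation, dtype=float)
    if np.any(z <= -500) or np.any(z >= 9000):
        raise ValueError("elevation outside (-500, 9000) m")
    # barometric formula with standard lapse rate 0.0065 K/m
    out = P0 * (1.0 - 0.0065 * z / 288.15) ** (9.80665 * 0.028963 / (RGAS * 0.0065))
    return float(out) if np.ndim(out) == 0 else out


def _arrhenius(x25, dha, t_c):
    tk = np.asarray(t_c, dtype=float) + KELVIN
    return x25 * np.exp(dha * (tk - T25) / (T25 * RGAS * tk))


def _viscosity_water(t_c):
    """Dynamic viscosity of water (Pa s), Vogel-Fulcher-Tammann form."""
    tk = np.asarray(t_c, dtype=float) + KELVIN
    return 2.414e-5 * 10.0 ** (247.8 / (tk - 140.0))


def photosynthesis_coefficients(t_g, pressure, constants: OptimalityConstants = DEFAULT_CONSTANTS):
    """Photorespiratory compensation point gammastar (Pa), effective
    Michaelis coefficient K = Kc (1 + pO2/Ko) (Pa) and relative water
    viscosity eta* at temperature ``t_g`` (degC) and ``pressure`` (Pa)."""
    t_g = np.asarray(t_g, dtype=float)
    if np.any(t_g <= -20) or np.any(t_g >= 50):
        raise ValueError("t_g outside (-20, 50) degC")
    gammastar = _arrhenius(constants.gammastar25, constants.dha_gammastar, t_g) * (
        np.asarray(pressure) / P0
    )
    kc = _arrhenius(constants.kc25, constants.dha_kc, t_g)
    ko = _arrhenius(constants.ko25, constants.dha_ko, t_g)
    po2 = constants.o2_mole_frac * np.asarray(pressure, dtype=float)
    K = kc * (1.0 + po2 / ko)
    eta_star = _viscosity_water(t_g) / _viscosity_water(25.0)
    return gammastar, K, eta_star


def optimal_chi(env: OptimalityEnv, constants: OptimalityConstants = DEFAULT_CONSTANTS):
    """Least-cost internal/ambient CO2 ratio and the CO2 limitation terms.

    Returns ``(pressure, gammastar, K, eta_star, xi, chi, ci, m, mc)``
    where ci is in Pa.  Raises :class:`DegenerateEnvironmentError` when
    ci <= gammastar (no positive assimilation possible).
    """
    pressure = np.asarray(atmospheric_pressure(env.elevation), dtype=float)
    gammastar, K, eta_star = photosynthesis_coefficients(env.t_g, pressure, constants)
    d_pa = np.maximum(env.vpd * 1000.0, constants.vpd_floor_pa)
    ca_pa = env.ca * 1e-6 * pressure
    xi = np.sqrt(constants.beta_costratio * (K + gammastar) / (1.6 * eta_star))
    g_over_ca = gammastar / ca_pa
    chi = g_over_ca + (1.0 - g_over_ca) * xi / (xi + np.sqrt(d_pa))
    ci = chi * ca_pa
    if np.any(ci <= gammastar):
        raise DegenerateEnvironmentError(
            "internal CO2 at or below the compensation point"
        )
    m = (ci - gammastar) / (ci + 2.0 * gammastar)
    mc = (ci - gammastar) / (ci + K)
    return pressure, gammastar, K, eta_star, xi, chi, ci, m, mc


def omega_from_cost(c, m, theta):
    """Dimensionless omega of the Jmax optimisation, vectorised.

    Returns NaN where the cost is infeasible (no real positive optimum),
    so that calibration code can penalise rather than crash.
    """
    c = np.asarray(c, dtype=float)
    m = np.asarray(m, dtype=float)
    g = 4.0 * c / m
    with np.errstate(invalid="ignore", divide="ignore"):
        inner = (1.0 - theta) * (1.0 / (g * (1.0 - theta * g)) - 4.0 * theta)
        omega = np.where(
            (g > 0) & (g * theta < 1.0) & (inner >= 0),
            -(1.0 - 2.0 * theta) + np.sqrt(np.where(inner >= 0, inner, np.nan)),
            np.nan,
        )
        omega = np.where(omega > 0, omega, np.nan)
    return omega


def vcmax_from_omega(omega, m, mc, par, theta, phi0):
    """Vcmax at growing-season temperature from omega and the CO2 terms."""
    omega_star = 1.0 + omega - np.sqrt((1.0 + omega) ** 2 - 4.0 * theta * omega)
    return phi0 * np.asarray(par, dtype=float) * (m / mc) * omega_star / (8.0 * theta)


def optimal_vcmax(
    env: OptimalityEnv,
    cost: CostConstant | np.ndarray | float = CostConstant(),
    constants: OptimalityConstants = DEFAULT_CONSTANTS,
) -> OptimalityInternals:
    """Full optimality solution: chi, omega, Jmax and Vcmax at T_g.

    ``cost`` may be a :class:`CostConstant` or a per-site array of unit
    costs.  Raises :class:`CostInfeasibleError` if any cost admits no real
    optimum.
    """
    c = cost.c if isinstance(cost, CostConstant) else np.asarray(cost, dtype=float)
    pressure, gammastar, K, eta_star, xi, chi, ci, m, mc = optimal_chi(env, constants)
    omega = omega_from_cost(c, m, constants.theta)
    if np.any(np.isnan(omega)):
        raise CostInfeasibleError(
            f"cost c={np.asarray(c)[np.isnan(np.atleast_1d(omega))] if np.ndim(c) else c} "
            "yields no real positive omega"
        )
    omega_star = 1.0 + omega - np.sqrt((1.0 + omega) ** 2 - 4.0 * constants.theta * omega)
    jmax = constants.phi0 * env.par * omega
    vcmax = vcmax_from_omega(omega, m, mc, env.par, constants.theta, constants.phi0)
    return OptimalityInternals(
        pressure=pressure,
        gammastar=gammastar,
        K=K,
        eta_star=eta_star,
        xi=xi,
        chi=chi,
        ci=ci,
        m=m,
        mc=mc,
        omega=omega,
        omega_star=omega_star,
        theta=constants.theta,
        phi0=constants.phi0,
        beta_costratio=constants.beta_costratio,
        jmax=jmax,
        vcmax=vcmax,
    )


def predict_vcmax25_optimality(
    env: OptimalityEnv,
    cost=CostConstant(),
    constants: OptimalityConstants = DEFAULT_CONSTANTS,
    kinetics: KineticsParams = DEFAULT_PARAMS,
):
    """Optimality Vcmax converted from T_g to 25 degC with the peaked
    Arrhenius scalar (entropy term acclimated to T_g)."""
    internals = optimal_vcmax(env, cost, constants)
    vc25 = convert_vcmax(internals.vcmax, env.t_g, 25.0, env.t_g, kinetics)
    return vc25, internals


def light_limited_net_gain(jmax, env_m, phi0_I, c, theta):
    """Objective of the Jmax optimisation: m * J/4 - c * Jmax, with the
    non-rectangular-hyperbola electron transport rate

        J = (phi0 I + Jmax - sqrt((phi0 I + Jmax)^2 - 4 theta phi0 I Jmax)) / (2 theta).

    Used by tests as an independent brute-force oracle for the closed form.
    """
    jmax = np.asarray(jmax, dtype=float)
    s = phi0_I + jmax
    j = (s - np.sqrt(s * s - 4.0 * theta * phi0_I * jmax)) / (2.0 * theta)
    return env_m * j / 4.0 - c * jmax
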