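"""Peaked (modified) Arrhenius temperature response of RuBisCO carboxylation.

The maximum carboxylation rate of a leaf measured at one temperature is
converted to any other temperature with a two-part scalar: an Arrhenius
activation term and a high-temperature deactivation ratio whose entropy
term acclimates linearly to the site's mean growing-season temperature
(Kattge & Knorr style acclimation).  All temperatures are in degrees
Celsius at the interface; Kelvin conversion uses +273.15 exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "KineticsParams",
    "entropy_term",
    "temperature_scalar",
    "convert_vcmax",
    "optimum_temperature",
]

#: Physically plausible leaf/air temperature range (deg C).  The exponential
#: deactivation term overflows silently far outside it, so we raise instead.
T_MIN, T_MAX = -50.0, 60.0


@dataclass(frozen=True)
class KineticsParams:
    """Enzyme-kinetic constants of the peaked Arrhenius response.

    Attributes
    ----------
    Ha : float
        Activation energy (J mol-1).
    Hd : float
        Deactivation energy (J mol-1).
    R : float
        Universal gas constant (J mol-1 K-1).
    deltaS_slope, deltaS_intercept : float
        Linear acclimation of the entropy term to growing-season
        temperature: dS = slope * Tg + intercept (J mol-1 K-1 per deg C
        and J mol-1 K-1).
    """

    Ha: float = 71_513.0
    Hd: float = 200_000.0
    R: float = 8.314
    deltaS_slope: float = -1.07
    deltaS_intercept: float = 668.39

    def __post_init__(self) -> None:
        if not (self.Hd > self.Ha > 0):
            raise ValueError(f"require Hd > Ha > 0, got Ha={self.Ha}, Hd={self.Hd}")
        if self.R <= 0:
            raise ValueError("gas constant must be positive")


DEFAULT_PARAMS = KineticsParams()


def entropy_term(t_g, params: KineticsParams = DEFAULT_PARAMS):
    """Entropy term dS (J mol-1 K-1) acclimated to growing-season temperature.

    dS = deltaS_slope * t_g + deltaS_intercept.
    """
    t_g = np.asarray(t_g, dtype=float)
    if not np.all(np.isfinite(t_g)):
        raise ValueError("t_g must be finite")
    out = params.deltaS_slope * t_g + params.deltaS_intercept
    return float(out) if out.ndim == 0 else out


def _check_range(name, t):
    t = np.asarray(t, dtype=float)
    if np.any(~np.isfinite(t)) or np.any(t <= T_MIN) or np.any(t >= T_MAX):
        raise ValueError(f"{name} outside physical range ({T_MIN}, {T_MAX}) deg C")
    return t


def temperature_scalar(t0, t1, deltaS, params: KineticsParams = DEFAULT_PARAMS):
    """Scalar f(T0, T1) converting Vcmax from temperature T0 to T1.

    f = exp(Ha (T1-T0) / (R Tk0 Tk1)) * (1 + exp((Tk0 dS - Hd)/(R Tk0)))
                                       / (1 + exp((Tk1 dS - Hd)/(R Tk1)))

    with Tk = T + 273.15.  f(T, T) = 1 and f factorises multiplicatively:
    f(a, b) * f(b, c) = f(a, c).
    """
    t0 = _check_range("t0", t0)
    t1 = _check_range("t1", t1)
    deltaS = np.asarray(deltaS, dtype=float)
    tk0 = t0 + 273.15
    tk1 = t1 + 273.15
    arrhenius = np.exp(params.Ha * (t1 - t0) / (params.R * tk0 * tk1))
    inhib0 = 1.0 + np.exp((tk0 * deltaS - params.Hd) / (params.R * tk0))
    inhib1 = 1.0 + np.exp((tk1 * deltaS - params.Hd) / (params.R * tk1))
    f = arrhenius * inhib0 / inhib1
    if np.any(~np.isfinite(f)):
        raise FloatingPointError(
            f"non-finite temperature scalar for t0={t0}, t1={t1}, deltaS={deltaS}"
        )
    return float(f) if np.ndim(f) == 0 else f


def convert_vcmax(v, t_from, t_to, t_g, params: KineticsParams = DEFAULT_PARAMS):
    """Convert Vcmax (umol m-2 s-1) from ``t_from`` to ``t_to``.

    The entropy term is evaluated at the site growing-season temperature
    ``t_g`` for both directions, so conversions chain exactly:
    Tmeas -> 25 -> Tg equals Tmeas -> Tg to machine precision.
    """
    v = np.asarray(v, dtype=float)
    if np.any(v <= 0):
        raise ValueError("Vcmax must be strictly positive")
    f = temperature_scalar(t_from, t_to, entropy_term(t_g, params), params)
    out = v * f
    return float(out) if np.ndim(out) == 0 else out


def derive_vcmax_columns(df, params: KineticsParams = DEFAULT_PARAMS):
    """Add field-derived ``vcmax_25`` and ``vcmax_tg`` columns to a table.

    Both are converted from ``vcmax_tmeas`` with the peaked Arrhenius
    scalar; the entropy term uses the site growing-season temperature for
    both steps, so Tmeas -> 25 -> Tg chains exactly.
    """
    out = df.copy()
    ds = entropy_term(out["t_g"].to_numpy(float), params)
    v = out["vcmax_tmeas"].to_numpy(float)
    tm = out["t_meas"].to_numpy(float)
    tg = out["t_g"].to_numpy(float)
    out["vcmax_25"] = v * temperature_scalar(tm, 25.0, ds, params)
    out["vcmax_tg"] = v * temperature_scalar(tm, tg, ds, params)
    return out


def optimum_temperature(t_g, params: KineticsParams = DEFAULT_PARAMS):
    """Temperature (deg C) maximising f(25, .) at the dS implied by ``t_g``.

    Closed form: T_opt(K) = Hd / (dS - R ln(Ha / (Hd - Ha))).  Warmer
    growing seasons (smaller dS) shift the optimum upward — the
    acclimation direction of the peaked response.
    """
    deltaS = np.asarray(entropy_term(t_g, params), dtype=float)
    denom = deltaS - params.R * np.log(params.Ha / (params.Hd - params.Ha))
    if np.any(denom <= 0):
        raise ValueError("dS - R ln(Ha/(Hd-Ha)) must be positive")
    out = params.Hd / denom - 273.15
    return float(out) if np.ndim(out) == 0 else out
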