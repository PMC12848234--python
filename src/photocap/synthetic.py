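"""Synthetic site tables with known ground truth.

The generator emulates the statistical structure of a global leaf
gas-exchange compilation: correlated climate, edaphic and leaf-trait
covariates (Gaussian copula with mixed marginals), site-level replicate
measurements with leaf-temperature jitter, and two generative modes:

``regression_truth``
    Site Vcmax25 is a linear function of covariates plus Gaussian site
    noise (the world the statistical track assumes).
``optimality_truth``
    A linear cost model sets the site unit cost c_i; Vcmax at
    growing-season temperature comes from the optimality model and is
    back-converted to the measurement temperature (the world the
    dynamic-cost track assumes).

Default effect signs mirror the qualitative global pattern: leaf N and
soil pH positive, VPD and elevation negative, precipitation positive.
Defaults are the study conditions of the test-suite experiments; every
knob is a config field.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .data_model import SiteTable
from .kinetics import DEFAULT_PARAMS, KineticsParams, entropy_term, temperature_scalar
from .optimality import DEFAULT_CONSTANTS, OptimalityEnv, omega_from_cost, optimal_vcmax

__all__ = ["GeneratorConfig", "generate", "null_shuffle"]

# latent order of the Gaussian copula
_LATENTS = [
    "t_g", "vpd", "par", "ca", "elevation", "precipitation",
    "soil_ph", "soil_c", "soil_n", "alpha_pt", "cec", "bulk_density",
    "tex1", "tex2", "tex3", "lma", "na",
]

#: cross-correlations of the latent Gaussian (symmetrised; rest zero)
_DEFAULT_CORR = {
    ("t_g", "vpd"): 0.5,
    ("t_g", "par"): 0.4,
    ("t_g", "elevation"): -0.4,
    ("t_g", "precipitation"): 0.4,
    ("vpd", "precipitation"): -0.5,
    ("vpd", "alpha_pt"): -0.5,
    ("precipitation", "alpha_pt"): 0.5,
    ("precipitation", "soil_ph"): -0.4,
    ("soil_c", "soil_n"): 0.8,
    ("cec", "soil_c"): 0.4,
    ("na", "soil_n"): 0.3,
    ("lma", "na"): 0.5,
}


def _corr_matrix(overrides=None) -> np.ndarray:
    corr = dict(_DEFAULT_CORR)
    if overrides:
        corr.update(overrides)
    C = np.eye(len(_LATENTS))
    idx = {n: i for i, n in enumerate(_LATENTS)}
    for (a, b), r in corr.items():
        C[idx[a], idx[b]] = C[idx[b], idx[a]] = r
    w, V = np.linalg.eigh(C)
    if w.min() < 1e-8:  # nudge to the nearest PSD matrix
        w = np.clip(w, 1e-8, None)
        C = V @ np.diag(w) @ V.T
        D = np.sqrt(np.diag(C))
        C = C / np.outer(D, D)
    return C


def _lognorm(u, median, sigma):
    return median * np.exp(sigma * norm.ppf(u))


def _marginals(u: np.ndarray) -> pd.DataFrame:
    """Map copula uniforms (n, len(_LATENTS)) to covariates in native units."""
    col = {n: u[:, i] for i, n in enumerate(_LATENTS)}
    df = pd.DataFrame(
        {
            "t_g": np.clip(norm.ppf(col["t_g"], loc=16.0, scale=7.0), 0.0, 30.0),
            "vpd": np.clip(_lognorm(col["vpd"], 0.9, 0.5), 0.05, 4.0),
            "par": np.clip(_lognorm(col["par"], 700.0, 0.4), 150.0, 2300.0),
            "ca": norm.ppf(col["ca"], loc=400.0, scale=8.0),
            "elevation": np.clip(_lognorm(col["elevation"], 300.0, 1.0), 0.0, 4500.0),
            "precipitation": np.clip(_lognorm(col["precipitation"], 1000.0, 0.5), 100.0, 4000.0),
            "soil_ph": 4.0 + 4.5 * col["soil_ph"],
            "soil_c": _lognorm(col["soil_c"], 20.0, 0.6),
            "soil_n": _lognorm(col["soil_n"], 1.8, 0.6),
            "alpha_pt": 0.3 + 1.0 * col["alpha_pt"],
            "cec": _lognorm(col["cec"], 15.0, 0.5),
            "bulk_density": norm.ppf(col["bulk_density"], loc=1.3, scale=0.15),
            "lma": _lognorm(col["lma"], 90.0, 0.4),
            "na": _lognorm(col["na"], 1.7, 0.35),
        }
    )
    df["soil_cn"] = df["soil_c"] / df["soil_n"]
    w = np.exp(0.8 * norm.ppf(u[:, [_LATENTS.index(t) for t in ("tex1", "tex2", "tex3")]]))
    frac = 100.0 * w / w.sum(axis=1, keepdims=True)
    df["silt"], df["clay"], df["sand"] = frac[:, 0], frac[:, 1], frac[:, 2]
    return df


@dataclass
class GeneratorConfig:
    """Study conditions of a synthetic experiment.

    Coefficients (``gammas`` for regression truth, ``cost_betas`` for
    optimality truth) act on covariates z-scored over the generated
    sites; the truth table records the equivalent raw-unit coefficients.
    Noise channels: ``site_noise_sd`` (biological, additive umol for
    regression truth, multiplicative fraction for optimality truth) and
    ``measurement_noise_sd`` (replicate-level, multiplicative fraction).
    """

    n_sites: int = 200
    measurements_per_site: int = 3
    seed: int = 0
    mode: str = "regression_truth"
    corr_overrides: dict | None = None
    # regression truth
    gamma0: float = 70.0
    gammas: dict = field(
        default_factory=lambda: {
            "na": 16.0, "vpd": -10.0, "soil_ph": 8.0, "precipitation": 7.0, "elevation": -8.0
        }
    )
    site_noise_sd: float = 10.0
    # optimality truth
    cost_beta0: float = 0.053
    cost_betas: dict = field(
        default_factory=lambda: {
            "soil_ph": -0.008, "alpha_pt": 0.005, "soil_n": -0.004, "cec": 0.003
        }
    )
    optimality_noise_sd: float = 0.05
    # measurement level
    measurement_noise_sd: float = 0.05
    t_meas_offset_mean: float = 2.0
    t_meas_offset_sd: float = 3.0

    def __post_init__(self) -> None:
        if self.mode not in ("regression_truth", "optimality_truth"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if min(self.site_noise_sd, self.optimality_noise_sd, self.measurement_noise_sd) < 0:
            raise ValueError("noise SDs must be non-negative")


def generate(
    config: GeneratorConfig,
    kinetics: KineticsParams = DEFAULT_PARAMS,
    constants=DEFAULT_CONSTANTS,
) -> tuple[SiteTable, pd.DataFrame]:
    """Draw a measurement-level :class:`SiteTable` and its ground truth.

    The truth table has one row per site (true Vcmax25, true Vcmax(Tg),
    true cost where applicable) and carries the generating coefficients
    in ``truth.attrs``.
    """
    rng = np.random.default_rng(config.seed)
    C = _corr_matrix(config.corr_overrides)
    L = np.linalg.cholesky(C)
    z = rng.standard_normal((config.n_sites, len(_LATENTS))) @ L.T
    u = norm.cdf(z)
    cov = _marginals(u)
    mu, sd = cov.mean(), cov.std(ddof=0)

    def zscore(names):
        if not names:
            return np.zeros((config.n_sites, 0))
        return np.column_stack([(cov[n] - mu[n]) / sd[n] for n in names])

    site_id = np.array([f"S{i:04d}" for i in range(config.n_sites)])
    tg = cov["t_g"].to_numpy()
    attrs = {"mode": config.mode, "seed": config.seed}

    if config.mode == "regression_truth":
        names = list(config.gammas)
        g = np.array([config.gammas[n] for n in names])
        signal = zscore(names) @ g
        vc25_true = config.gamma0 + signal + rng.normal(0.0, config.site_noise_sd, config.n_sites)
        vc25_true = np.maximum(vc25_true, 5.0)
        vc25_site = vc25_true
        c_true = np.full(config.n_sites, np.nan)
        attrs["gamma_std"] = dict(config.gammas)
        attrs["gamma_raw"] = {n: config.gammas[n] / sd[n] for n in names}
        attrs["gamma0_raw"] = config.gamma0 - sum(
            config.gammas[n] * mu[n] / sd[n] for n in names
        )
        ds = entropy_term(tg, kinetics)
        vctg_true = vc25_true * temperature_scalar(25.0, tg, ds, kinetics)
    else:
        names = list(config.cost_betas)
        betas = {n: config.cost_betas[n] for n in names}
        env = OptimalityEnv(
            t_g=tg,
            par=cov["par"].to_numpy(),
            vpd=cov["vpd"].to_numpy(),
            ca=cov["ca"].to_numpy(),
            elevation=cov["elevation"].to_numpy(),
        )
        for attempt in range(4):
            b = np.array([betas[n] for n in names])
            c_true = config.cost_beta0 + zscore(names) @ b
            _, _, _, _, _, _, _, m, _ = _chi_terms(env, constants)
            feasible = np.isfinite(omega_from_cost(c_true, m, constants.theta))
            if (~feasible).mean() <= 0.01:
                break
            warnings.warn("infeasible costs for >1% of sites; narrowing betas")
            betas = {n: v / 2.0 for n, v in betas.items()}
        else:
            raise RuntimeError("could not find feasible cost coefficients")
        c_true = np.clip(c_true, 0.008, None)  # keep the residual <=1% feasible
        internals = optimal_vcmax(env, c_true, constants)
        vctg_true = internals.vcmax
        ds = entropy_term(tg, kinetics)
        vc25_true = vctg_true * temperature_scalar(tg, 25.0, ds, kinetics)
        noise = 1.0 + rng.normal(0.0, config.optimality_noise_sd, config.n_sites)
        vc25_site = vc25_true * np.maximum(noise, 0.05)
        attrs["cost_beta_std"] = betas
        attrs["cost_beta0"] = config.cost_beta0

    # measurement level: leaf-temperature jitter + replicate noise
    reps = config.measurements_per_site
    idx = np.repeat(np.arange(config.n_sites), reps)
    t_meas = np.clip(
        tg[idx] + rng.normal(config.t_meas_offset_mean, config.t_meas_offset_sd, len(idx)),
        -10.0, 50.0,
    )
    ds_m = entropy_term(tg[idx], kinetics)
    f_25_tmeas = temperature_scalar(25.0, t_meas, ds_m, kinetics)
    mnoise = 1.0 + rng.normal(0.0, config.measurement_noise_sd, len(idx))
    vcmax_tmeas = vc25_site[idx] * f_25_tmeas * np.maximum(mnoise, 0.05)

    df = cov.iloc[idx].reset_index(drop=True)
    df.insert(0, "site_id", site_id[idx])
    df["t_meas"] = t_meas
    df["vcmax_tmeas"] = vcmax_tmeas
    table = SiteTable(df, level="measurement", provenance={"generator": attrs})

    truth = pd.DataFrame(
        {
            "site_id": site_id,
            "vcmax_25_true": vc25_true,
            "vcmax_25_site": vc25_site,
            "vcmax_tg_true": vctg_true,
            "c_true": c_true,
        }
    )
    truth.attrs.update(attrs)
    return table, truth


def _chi_terms(env, constants):
    from .optimality import optimal_chi

    return optimal_chi(env, constants)


def null_shuffle(table: SiteTable, seed: int = 0) -> SiteTable:
    """Permute the response block across sites, breaking covariate links.

    The columns (vcmax_tmeas, t_meas and any derived vcmax columns) move
    together, so their marginal distributions and internal consistency
    are preserved while every covariate association is destroyed.
    """
    if table.level != "site-mean":
        raise ValueError("null_shuffle expects a site-mean table")
    rng = np.random.default_rng(seed)
    df = table.df.copy()
    perm = rng.permutation(len(df))
    block = [c for c in ("vcmax_tmeas", "t_meas", "vcmax_25", "vcmax_tg") if c in df.columns]
    df[block] = df[block].to_numpy()[perm]
    prov = dict(table.provenance)
    prov["null_shuffle_seed"] = seed
    return SiteTable(df, "site-mean", prov)
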