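"""Dynamic unit-cost model c_i = beta0 + sum_j beta_j x_ij and its calibration.

The total unit carbon cost c of the optimality model is either a global
constant (0.053) or a site-specific linear function of covariates under
three scenarios: the ten edaphic variables alone, all environmental
variables plus the two leaf traits, or the five most important variables
from the statistical track (leaf N, VPD, soil pH, precipitation,
elevation).

Coefficients are fitted with a real-coded genetic algorithm (tournament
selection, blend crossover, Gaussian mutation, elitism) minimising the
RMSE between observed and optimality-modelled Vcmax at growing-season
temperature, inside a repeated k-fold cross-validation.  Out-of-fold
predictions are averaged over the repetitions to give one ensemble
prediction per site.

Covariates are z-score standardised using the calibration fold's means
and SDs only, so coefficient bounds are scale-free and no information
leaks from validation folds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize

from . import data_model as dm
from .kinetics import KineticsParams, DEFAULT_PARAMS
from .optimality import (
    DEFAULT_CONSTANTS,
    OptimalityConstants,
    OptimalityEnv,
    omega_from_cost,
    optimal_chi,
)

__all__ = [
    "CostModel",
    "CVScheme",
    "GAConfig",
    "site_cost",
    "scenario_covariates",
    "fit_cost_ga",
    "DynamicCostOptimality",
    "DynamicCostResults",
]

SCENARIOS = ("constant", "edaphic", "env_traits", "top5")


@dataclass
class CostModel:
    """Linear cost model: c = beta0 + betas . x (optionally standardised x)."""

    scenario: str
    beta0: float
    betas: dict = field(default_factory=dict)
    covariates: list = field(default_factory=list)
    feasible_c_bounds: tuple = (0.005, 0.3)
    cov_means: dict | None = None  # standardisation from the calibration fold
    cov_sds: dict | None = None

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.scenario == "constant" and self.betas:
            raise ValueError("constant scenario admits no covariate coefficients")
        missing = set(self.betas) - set(self.covariates)
        if missing:
            raise ValueError(f"betas for covariates not listed: {sorted(missing)}")

    def cost_array(self, df: pd.DataFrame) -> np.ndarray:
        """Vector of c_i over the rows of ``df`` (flags nothing, no clamping)."""
        c = np.full(len(df), self.beta0, dtype=float)
        for name in self.covariates:
            if name not in df.columns:
                raise dm.SchemaError(f"covariate {name!r} absent from table")
            x = df[name].to_numpy(dtype=float)
            if self.cov_means is not None:
                x = (x - self.cov_means[name]) / self.cov_sds[name]
            c += self.betas.get(name, 0.0) * x
        return c


def site_cost(model: CostModel, record) -> float:
    """Unit cost c_i for one site record (mapping or pandas row)."""
    df = pd.DataFrame([dict(record)])
    c = float(model.cost_array(df)[0])
    lo, hi = model.feasible_c_bounds
    if not (lo <= c <= hi):
        warnings.warn(f"site cost {c:.4g} outside feasible bounds [{lo}, {hi}]")
    return c


def scenario_covariates(scenario: str, table_schema=None) -> list[str]:
    """Ordered covariate names entering the cost model for a scenario."""
    if scenario == "constant":
        names = []
    elif scenario == "edaphic":
        names = list(dm.EDAPHIC_VARS)
    elif scenario == "env_traits":
        names = list(dm.CLIMATE_VARS) + list(dm.EDAPHIC_VARS) + list(dm.TRAIT_VARS)
    elif scenario == "top5":
        names = ["na", "vpd", "soil_ph", "precipitation", "elevation"]
    else:
        raise ValueError(f"unknown scenario {scenario!r}")
    if table_schema is not None:
        missing = [n for n in names if n not in table_schema]
        if missing:
            raise dm.SchemaError(f"schema lacks covariates {missing}")
    return names


@dataclass(frozen=True)
class CVScheme:
    """Repeated k-fold cross-validation: every record is validated exactly
    once per repetition; folds are a fresh seeded random partition each
    repetition (no stratification)."""

    n_folds: int = 5
    n_repetitions: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("need at least 2 folds")

    def iter_folds(self, n: int):
        """Yield (repetition, fold, calibration_idx, validation_idx)."""
        rng = np.random.default_rng(self.seed)
        for rep in range(self.n_repetitions):
            perm = rng.permutation(n)
            folds = np.array_split(perm, self.n_folds)
            for k, val in enumerate(folds):
                cal = np.setdiff1d(perm, val)
                yield rep, k, cal, val


@dataclass(frozen=True)
class GAConfig:
    """Real-coded GA hyperparameters (all configurable; defaults chosen for
    reproducible desk-scale runs)."""

    population_size: int = 100
    n_generations: int = 800
    crossover_rate: float = 0.7
    mutation_scale: float = 0.10  # initial sigma as a fraction of each bound range
    mutation_decay: float = 0.002  # final sigma as a fraction of the initial one
    mutation_prob: float = 0.2  # per-gene mutation probability
    tournament_size: int = 3
    elitism: int = 1
    polish: bool = True  # Nelder-Mead refinement of the final best individual
    polish_maxiter: int = 4000
    n_restarts: int = 3  # independent GA runs; best final fitness wins
    beta0_bounds: tuple = (0.005, 0.3)
    beta_bounds: tuple = (-0.2, 0.2)  # on standardised covariates
    infeasible_penalty: float = 1.0e6  # squared-error charged per infeasible site
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 10:
            raise ValueError("population_size must be >= 10")


def _ga_minimize(fitness, bounds, cfg: GAConfig, rng, x0=None) -> tuple[np.ndarray, float]:
    """Minimise ``fitness(pop) -> (pop_size,)`` over box ``bounds``.

    Runs ``cfg.n_restarts`` independent evolutionary searches (the RMSE
    surface of the cost calibration is multimodal — a mirrored basin with
    inflated intercept fits almost as well) and keeps the best final
    fitness.  ``x0`` optionally seeds one individual of every initial
    population (the calibration passes the constant-cost null here).
    Vectorised over the population.
    """
    best_x, best_f = None, np.inf
    for _ in range(max(cfg.n_restarts, 1)):
        x, f = _ga_run(fitness, bounds, cfg, rng, x0)
        if f < best_f:
            best_x, best_f = x, f
    return best_x, best_f


def _ga_run(fitness, bounds, cfg: GAConfig, rng, x0=None) -> tuple[np.ndarray, float]:
    lo, hi = bounds[:, 0], bounds[:, 1]
    npar = len(lo)
    pop = rng.uniform(lo, hi, size=(cfg.population_size, npar))
    if x0 is not None:
        pop[0] = np.clip(np.asarray(x0, dtype=float), lo, hi)
    fit = fitness(pop)
    for gen in range(cfg.n_generations):
        # annealed mutation: broad search early, fine-tuning late
        anneal = cfg.mutation_decay ** (gen / max(cfg.n_generations - 1, 1))
        # tournament selection
        idx = rng.integers(0, cfg.population_size, size=(cfg.population_size, cfg.tournament_size))
        winners = idx[np.arange(cfg.population_size), np.argmin(fit[idx], axis=1)]
        parents = pop[winners]
        # blend (BLX-0.5) crossover on consecutive pairs
        children = parents.copy()
        do_cx = rng.random(cfg.population_size // 2) < cfg.crossover_rate
        a = children[0::2][do_cx]
        b = children[1::2][do_cx]
        u = rng.uniform(-0.5, 1.5, size=a.shape)
        children[0::2][do_cx] = a + u * (b - a)
        children[1::2][do_cx] = b + u * (a - b)
        # gaussian mutation
        sigma = cfg.mutation_scale * anneal * (hi - lo)
        mut = rng.random(children.shape) < cfg.mutation_prob
        children = children + mut * rng.normal(0.0, 1.0, size=children.shape) * sigma
        children = np.clip(children, lo, hi)
        child_fit = fitness(children)
        # elitism: preserve the best of the previous generation
        elite_idx = np.argsort(fit)[: cfg.elitism]
        worst = np.argsort(child_fit)[::-1][: cfg.elitism]
        children[worst] = pop[elite_idx]
        child_fit[worst] = fit[elite_idx]
        pop, fit = children, child_fit
    best = int(np.argmin(fit))
    x_best, f_best = pop[best], float(fit[best])
    if cfg.polish:
        # memetic step: the evolutionary search localises the optimum basin,
        # a derivative-free simplex refines along the flat valley the GA
        # cannot resolve against its own selection noise
        res = scipy.optimize.minimize(
            lambda x: float(fitness(np.clip(x, lo, hi)[None, :])[0]),
            x_best,
            method="Nelder-Mead",
            options={"maxiter": cfg.polish_maxiter, "xatol": 1e-10, "fatol": 1e-12},
        )
        x_p = np.clip(res.x, lo, hi)
        f_p = float(fitness(x_p[None, :])[0])
        if f_p < f_best:
            x_best, f_best = x_p, f_p
    return x_best, f_best


class _OptimalityPrecomp:
    """Per-site optimality terms that do not depend on the cost c."""

    def __init__(self, df: pd.DataFrame, constants: OptimalityConstants):
        env = OptimalityEnv(
            t_g=df["t_g"].to_numpy(float),
            par=df["par"].to_numpy(float),
            vpd=df["vpd"].to_numpy(float),
            ca=df["ca"].to_numpy(float),
            elevation=df["elevation"].to_numpy(float),
        )
        (_, _, _, _, _, _, _, self.m, self.mc) = optimal_chi(env, constants)
        self.phi0_I = constants.phi0 * env.par
        self.theta = constants.theta

    def vcmax(self, c: np.ndarray) -> np.ndarray:
        """Vcmax(Tg) for cost array ``c`` with shape (..., n_sites); NaN where
        the cost is infeasible."""
        omega = omega_from_cost(c, self.m, self.theta)
        omega_star = 1.0 + omega - np.sqrt((1.0 + omega) ** 2 - 4.0 * self.theta * omega)
        return self.phi0_I * (self.m / self.mc) * omega_star / (8.0 * self.theta)


@dataclass
class DynamicCostResults:
    """Calibration output: fold-level models, out-of-fold ensemble
    predictions of Vcmax(Tg) and of the site cost c, and an RMSE log."""

    scenario: str
    models: list
    oof: pd.DataFrame  # site_id, vcmax_tg_obs, vcmax_tg_pred, c_pred
    fold_log: pd.DataFrame  # repetition, fold, rmse, failed
    n_failed_folds: int

    @property
    def ensemble_prediction(self) -> np.ndarray:
        return self.oof["vcmax_tg_pred"].to_numpy()

    def metrics(self, k: int | None = None):
        from .assessment import compute_metrics

        if k is None:
            k = 1 + len(self.models[0].covariates)
        return compute_metrics(
            self.oof["vcmax_tg_obs"].to_numpy(), self.ensemble_prediction, k=k
        )

    def summary(self) -> str:
        m = self.metrics()
        beta_mat = np.array(
            [[mod.beta0] + [mod.betas.get(n, 0.0) for n in mod.covariates] for mod in self.models]
        )
        names = ["beta0"] + list(self.models[0].covariates)
        lines = [
            f"Dynamic-cost optimality model (scenario: {self.scenario})",
            f"  folds fitted: {len(self.models)}  failed: {self.n_failed_folds}",
            f"  out-of-fold: r2={m.r2:.3f} bias={m.bias:.3f} rmse={m.rmse:.3f} aic={m.aic:.1f}",
            "  coefficient (mean +/- sd over folds, standardised covariates):",
        ]
        for j, name in enumerate(names):
            lines.append(f"    {name:>14s} {beta_mat[:, j].mean():+.4f} +/- {beta_mat[:, j].std():.4f}")
        return "\n".join(lines)


class DynamicCostOptimality:
    """Optimality model of Vcmax(Tg) with a site-specific unit cost.

    Parameters
    ----------
    table : SiteTable
        Site-mean table carrying ``vcmax_tg`` (observed, derived from the
        measurement temperature via the kinetics scalar) and the scenario's
        covariates.
    scenario : str
        One of ``constant``, ``edaphic``, ``env_traits``, ``top5``.
    """

    def __init__(
        self,
        table: dm.SiteTable,
        scenario: str = "edaphic",
        constants: OptimalityConstants = DEFAULT_CONSTANTS,
        kinetics: KineticsParams = DEFAULT_PARAMS,
    ):
        if table.level != "site-mean":
            raise ValueError("calibration requires a site-mean table")
        if "vcmax_tg" not in table.df.columns:
            raise dm.SchemaError("table lacks observed vcmax_tg (derive it first)")
        self.table = table
        self.scenario = scenario
        self.covariates = scenario_covariates(scenario, table.df.columns)
        self.constants = constants
        self.kinetics = kinetics
        df = table.df
        ok = df["vcmax_tg"].notna()
        for c in self.covariates + ["t_g", "par", "vpd", "ca", "elevation"]:
            ok &= df[c].notna()
        self.df = df.loc[ok].reset_index(drop=True)
        self.precomp = _OptimalityPrecomp(self.df, constants)
        self.observed = self.df["vcmax_tg"].to_numpy(float)

    def _fitness_factory(self, X: np.ndarray, obs: np.ndarray, precomp_idx: np.ndarray, ga: GAConfig):
        m = self.precomp.m[precomp_idx]
        mc = self.precomp.mc[precomp_idx]
        phi0_I = self.precomp.phi0_I[precomp_idx]
        theta = self.precomp.theta

        def fitness(pop: np.ndarray) -> np.ndarray:
            c = pop[:, [0]] + pop[:, 1:] @ X.T  # (pop, n_sites)
            omega = omega_from_cost(c, m[None, :], theta)
            omega_star = 1.0 + omega - np.sqrt((1.0 + omega) ** 2 - 4.0 * theta * omega)
            pred = phi0_I * (m / mc) * omega_star / (8.0 * theta)
            se = (pred - obs) ** 2
            se = np.where(np.isnan(se), ga.infeasible_penalty, se)
            return np.sqrt(se.mean(axis=1))

        return fitness

    def fit(self, ga: GAConfig = GAConfig(), cv: CVScheme = CVScheme()) -> DynamicCostResults:
        """Calibrate beta by GA under repeated k-fold CV.

        Returns fold-level models and per-site out-of-fold ensemble
        predictions (mean over repetitions).  Aborts if more than 10% of
        folds fail to find any feasible cost.
        """
        n = len(self.df)
        p = len(self.covariates)
        bounds = np.vstack([[ga.beta0_bounds], np.repeat([ga.beta_bounds], p, axis=0)])
        rng = np.random.default_rng(ga.seed)
        Xall = self.df[self.covariates].to_numpy(float) if p else np.empty((n, 0))

        pred_sum = np.zeros(n)
        pred_cnt = np.zeros(n)
        c_sum = np.zeros(n)
        models, log = [], []
        n_failed = 0
        for rep, fold, cal, val in cv.iter_folds(n):
            mu = Xall[cal].mean(axis=0) if p else np.empty(0)
            sd = Xall[cal].std(axis=0, ddof=0) if p else np.empty(0)
            sd = np.where(sd == 0, 1.0, sd)
            Zcal = (Xall[cal] - mu) / sd if p else Xall[cal]
            fitness = self._fitness_factory(Zcal, self.observed[cal], cal, ga)
            # one seeded individual: the constant-cost null the model nests
            null_x0 = np.concatenate([[0.053], np.zeros(p)])
            params, best_rmse = _ga_minimize(fitness, bounds, ga, rng, x0=null_x0)
            failed = best_rmse >= np.sqrt(ga.infeasible_penalty)
            log.append({"repetition": rep, "fold": fold, "rmse": best_rmse, "failed": failed})
            if failed:
                n_failed += 1
                continue
            model = CostModel(
                scenario=self.scenario,
                beta0=float(params[0]),
                betas={name: float(b) for name, b in zip(self.covariates, params[1:])},
                covariates=list(self.covariates),
                feasible_c_bounds=ga.beta0_bounds,
                cov_means={name: float(v) for name, v in zip(self.covariates, mu)} if p else None,
                cov_sds={name: float(v) for name, v in zip(self.covariates, sd)} if p else None,
            )
            models.append(model)
            # predict held-out sites with the fold's cost model
            Zval = (Xall[val] - mu) / sd if p else Xall[val]
            c_val = params[0] + (Zval @ params[1:] if p else np.zeros(len(val)))
            full_c = np.full(n, np.nan)
            full_c[val] = c_val
            pred_full = self.precomp.vcmax(full_c)
            pv = pred_full[val]
            feas = np.isfinite(pv)
            pred_sum[val[feas]] += pv[feas]
            pred_cnt[val[feas]] += 1
            c_sum[val[feas]] += c_val[feas]

        total_folds = cv.n_folds * cv.n_repetitions
        if n_failed > 0.10 * total_folds:
            raise RuntimeError(
                f"{n_failed}/{total_folds} folds failed to find a feasible cost"
            )
        with np.errstate(invalid="ignore"):
            oof = pd.DataFrame(
                {
                    "site_id": self.df["site_id"],
                    "vcmax_tg_obs": self.observed,
                    "vcmax_tg_pred": pred_sum / pred_cnt,
                    "c_pred": c_sum / pred_cnt,
                }
            )
        return DynamicCostResults(
            scenario=self.scenario,
            models=models,
            oof=oof,
            fold_log=pd.DataFrame(log),
            n_failed_folds=n_failed,
        )


def fit_cost_ga(
    table: dm.SiteTable,
    scenario: str,
    ga: GAConfig = GAConfig(),
    cv: CVScheme = CVScheme(),
    kinetics: KineticsParams = DEFAULT_PARAMS,
    constants: OptimalityConstants = DEFAULT_CONSTANTS,
) -> DynamicCostResults:
    """Functional entry point: calibrate the dynamic cost model on a table."""
    return DynamicCostOptimality(table, scenario, constants, kinetics).fit(ga, cv)
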