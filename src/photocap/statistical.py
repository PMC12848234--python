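"""Two-level statistical track for Vcmax at growing-season temperature.

Level 1 (kinetics only): every site shares one global-mean Vcmax25; the
site prediction is that mean times the peaked-Arrhenius scalar f(25, Tg).
Level 2 (kinetics + environment): site Vcmax25 is a multiple linear
regression on environmental variables and leaf traits, fitted by OLS
under repeated k-fold cross-validation; the out-of-fold Vcmax25
predictions are ensemble-averaged over repetitions and multiplied by
f(25, Tg).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import data_model as dm
from .cost_model import CVScheme
from .kinetics import DEFAULT_PARAMS, KineticsParams, entropy_term, temperature_scalar

__all__ = [
    "KineticsGlobalMean",
    "Level1Results",
    "EnvironmentalRegression",
    "Level2Results",
    "default_predictors",
]


def default_predictors(columns=None) -> list[str]:
    """All six climate + ten edaphic variables + LMA and leaf N (pre-VIF)."""
    names = list(dm.CLIMATE_VARS) + list(dm.EDAPHIC_VARS) + list(dm.TRAIT_VARS)
    if columns is not None:
        names = [n for n in names if n in columns]
    return names


def _f_25_to(t, t_g, params):
    return temperature_scalar(25.0, t, entropy_term(t_g, params), params)


def _check_site_mean(table: dm.SiteTable, need: list[str]):
    if table.level != "site-mean":
        raise ValueError("statistical track operates on site-mean tables")
    missing = [c for c in need if c not in table.df.columns]
    if missing:
        raise dm.SchemaError(f"table lacks columns {missing}")


@dataclass
class Level1Results:
    """Kinetics-only fit: one global-mean Vcmax25 drives every site."""

    global_mean_vcmax25: float
    predictions: pd.DataFrame  # site_id, vcmax_tg_obs, vcmax_tg_pred, vcmax_25_pred

    def metrics(self, target: str = "vcmax_tg"):
        from .assessment import compute_metrics

        return compute_metrics(
            self.predictions[f"{target}_obs"].to_numpy(),
            self.predictions[f"{target}_pred"].to_numpy(),
            k=1,
        )

    def summary(self) -> str:
        m = self.metrics()
        return (
            "Kinetics-only model (global-mean Vcmax25)\n"
            f"  global mean Vcmax25: {self.global_mean_vcmax25:.2f} umol m-2 s-1\n"
            f"  Vcmax(Tg): r2={m.r2:.3f} bias={m.bias:.3f} rmse={m.rmse:.3f} aic={m.aic:.1f}"
        )


class KineticsGlobalMean:
    """Level-1 model: global-average Vcmax25 plus enzyme kinetics."""

    def __init__(self, table: dm.SiteTable, kinetics: KineticsParams = DEFAULT_PARAMS):
        _check_site_mean(table, ["vcmax_25", "vcmax_tg", "t_g"])
        self.df = table.df.loc[
            table.df[["vcmax_25", "vcmax_tg", "t_g"]].notna().all(axis=1)
        ].reset_index(drop=True)
        self.kinetics = kinetics

    def fit(self) -> Level1Results:
        mean25 = float(self.df["vcmax_25"].mean())
        tg = self.df["t_g"].to_numpy(float)
        pred_tg = mean25 * _f_25_to(tg, tg, self.kinetics)
        predictions = pd.DataFrame(
            {
                "site_id": self.df["site_id"],
                "vcmax_25_obs": self.df["vcmax_25"],
                "vcmax_25_pred": mean25,
                "vcmax_tg_obs": self.df["vcmax_tg"],
                "vcmax_tg_pred": pred_tg,
            }
        )
        return Level1Results(global_mean_vcmax25=mean25, predictions=predictions)


def _drop_aliased(X: np.ndarray, names: list[str]):
    """Remove linearly dependent columns, keeping earlier-listed ones.

    Greedy scan in column order: a column is kept only if it increases
    the rank of the design built so far (so the intercept, listed first,
    always survives; e.g. with silt+clay+sand = 100 the last texture
    column is the one dropped)."""
    if X.shape[1] == 0:
        return X, names
    # scale columns so the rank tolerance is scale-free
    norms = np.linalg.norm(X, axis=0)
    norms[norms == 0] = 1.0
    Xs = X / norms
    keep: list[int] = []
    rank = 0
    for j in range(X.shape[1]):
        cand = Xs[:, keep + [j]]
        if np.linalg.matrix_rank(cand, tol=1e-8) > rank:
            keep.append(j)
            rank += 1
    if len(keep) < X.shape[1]:
        dropped = [names[i] for i in range(len(names)) if i not in keep]
        warnings.warn(f"dropping aliased predictor columns: {dropped}")
    return X[:, keep], [names[i] for i in keep]


@dataclass
class Level2Results:
    """Environment+traits regression: ensemble coefficients and out-of-fold
    predictions of Vcmax25 and Vcmax(Tg)."""

    predictors: list
    coef_table: pd.DataFrame  # per-fold intercept and coefficients
    predictions: pd.DataFrame

    @property
    def coefficients(self) -> pd.Series:
        return self.coef_table.mean(axis=0)

    def metrics(self, target: str = "vcmax_tg"):
        from .assessment import compute_metrics

        return compute_metrics(
            self.predictions[f"{target}_obs"].to_numpy(),
            self.predictions[f"{target}_pred"].to_numpy(),
            k=1 + len(self.predictors),
        )

    def summary(self) -> str:
        mt = self.metrics("vcmax_tg")
        m25 = self.metrics("vcmax_25")
        lines = [
            "Kinetics + environment/traits regression (level 2)",
            f"  predictors: {', '.join(self.predictors) or '(intercept only)'}",
            f"  Vcmax(Tg):  r2={mt.r2:.3f} bias={mt.bias:.3f} rmse={mt.rmse:.3f} aic={mt.aic:.1f}",
            f"  Vcmax25:    r2={m25.r2:.3f} bias={m25.bias:.3f} rmse={m25.rmse:.3f} aic={m25.aic:.1f}",
            "  coefficients (mean over folds):",
        ]
        for name, val in self.coefficients.items():
            lines.append(f"    {name:>14s} {val:+.4g}")
        return "\n".join(lines)


class EnvironmentalRegression:
    """Level-2 model: OLS of site Vcmax25 on environment and leaf traits.

    With ``cv=None`` the regression is fitted once on the full table
    (in-sample predictions); with a :class:`CVScheme` the predictions are
    out-of-fold ensemble means over the repetitions.
    """

    def __init__(
        self,
        table: dm.SiteTable,
        predictors: list[str] | None = None,
        kinetics: KineticsParams = DEFAULT_PARAMS,
    ):
        if predictors is None:
            predictors = default_predictors(table.df.columns)
        _check_site_mean(table, ["vcmax_25", "vcmax_tg", "t_g"] + list(predictors))
        cols = ["vcmax_25", "vcmax_tg", "t_g"] + list(predictors)
        self.df = table.df.loc[table.df[cols].notna().all(axis=1)].reset_index(drop=True)
        self.predictors = list(predictors)
        self.kinetics = kinetics

    def _design(self, idx) -> np.ndarray:
        X = self.df.iloc[idx][self.predictors].to_numpy(float)
        return np.column_stack([np.ones(len(idx)), X])

    def fit(self, cv: CVScheme | None = CVScheme()) -> Level2Results:
        n = len(self.df)
        y = self.df["vcmax_25"].to_numpy(float)
        names = ["intercept"] + self.predictors
        coef_rows = []
        if cv is None:
            X, kept = _drop_aliased(self._design(np.arange(n)), names)
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            pred25 = X @ beta
            coef_rows.append(dict(zip(kept, beta)))
        else:
            if n < cv.n_folds:
                raise ValueError("fewer sites than folds")
            pred_sum = np.zeros(n)
            pred_cnt = np.zeros(n)
            for rep, fold, cal, val in cv.iter_folds(n):
                Xc, kept = _drop_aliased(self._design(cal), names)
                beta, *_ = np.linalg.lstsq(Xc, y[cal], rcond=None)
                keep_idx = [names.index(nm) for nm in kept]
                Xv = self._design(val)[:, keep_idx]
                pred_sum[val] += Xv @ beta
                pred_cnt[val] += 1
                coef_rows.append(dict(zip(kept, beta)))
            pred25 = pred_sum / pred_cnt
        tg = self.df["t_g"].to_numpy(float)
        pred_tg = pred25 * _f_25_to(tg, tg, self.kinetics)
        predictions = pd.DataFrame(
            {
                "site_id": self.df["site_id"],
                "vcmax_25_obs": y,
                "vcmax_25_pred": pred25,
                "vcmax_tg_obs": self.df["vcmax_tg"],
                "vcmax_tg_pred": pred_tg,
            }
        )
        coef_table = pd.DataFrame(coef_rows).fillna(0.0)
        return Level2Results(
            predictors=self.predictors, coef_table=coef_table, predictions=predictions
        )
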