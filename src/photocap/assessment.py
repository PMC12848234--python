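"""Model assessment: metrics, collinearity pruning, multimodel importance.

Four metrics summarise every model comparison: squared Pearson
correlation r2, residual bias, RMSE, and an AIC computed on the RMSE
scale, AIC = 2 k + n ln(RMSE^2) (natural logarithm).  Variable
importance follows the multimodel-inference recipe: every subset of the
candidate predictors is fitted by OLS, ranked by small-sample corrected
AIC, converted to Akaike weights, and a variable's importance is the sum
of the weights of the models containing it (0.8 cut-off for "important").
Collinearity is handled upstream by iterative VIF pruning (threshold 10)
followed by pairwise-correlation pruning (threshold |r| 0.7).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.outliers_influence import variance_inflation_factor

__all__ = [
    "Metrics",
    "compute_metrics",
    "vif_prune",
    "exhaustive_selection",
    "SelectionResult",
    "partial_regression",
    "PartialRegression",
]


@dataclass(frozen=True)
class Metrics:
    """r2 (squared Pearson), bias = mean(pred - obs), RMSE, and
    AIC = 2k + n ln(RMSE^2)."""

    r2: float
    bias: float
    rmse: float
    aic: float
    n: int
    k: int


def compute_metrics(observed, predicted, k: int) -> Metrics:
    """Evaluate predictions against observations.

    ``k`` is the number of model parameters entering the AIC (regression
    coefficients including the intercept; 1 for the kinetics-only model).
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1 or obs.size == 0:
        raise ValueError("observed and predicted must be equal-length 1-D vectors")
    n = obs.size
    if np.std(obs) == 0 or np.std(pred) == 0:
        raise ValueError("r2 undefined for zero-variance vector")
    r = np.corrcoef(obs, pred)[0, 1]
    resid = pred - obs
    rmse = float(np.sqrt(np.mean(resid**2)))
    aic = 2.0 * k + n * np.log(rmse**2) if rmse > 0 else -np.inf
    return Metrics(r2=float(r * r), bias=float(resid.mean()), rmse=rmse, aic=float(aic), n=n, k=k)


def _as_frame(table):
    return table.df if hasattr(table, "df") else table


def vif_prune(table, candidates, vif_threshold=10.0, corr_threshold=0.7):
    """Iteratively prune collinear predictors.

    Phase 1 removes the variable with the largest variance inflation
    factor while any VIF >= ``vif_threshold``.  Phase 2 scans remaining
    pairs with |r| >= ``corr_threshold`` (strongest pair first) and drops
    the member with the larger mean absolute correlation to all other
    survivors (ties keep the earlier-listed variable).

    Returns ``(retained, trail)`` where ``trail`` logs each removal.
    """
    df = _as_frame(table)[list(candidates)].dropna()
    if len(candidates) < 2:
        raise ValueError("need at least two candidate predictors")
    if len(df) <= len(candidates):
        raise ValueError("need more observations than candidates")
    keep = list(candidates)
    trail = []
    while len(keep) >= 2:
        X = np.column_stack([np.ones(len(df))] + [df[c].to_numpy(float) for c in keep])
        with np.errstate(divide="ignore"):
            vifs = np.array(
                [variance_inflation_factor(X, j + 1) for j in range(len(keep))]
            )
        # drop the largest VIF; exact ties (e.g. all infinite under perfect
        # collinearity) drop the later-listed variable
        mx = vifs.max()
        if mx < vif_threshold:
            break
        tied = np.flatnonzero(np.isinf(vifs) if np.isinf(mx) else vifs >= mx * (1 - 1e-12))
        worst = int(tied[-1])
        trail.append({"variable": keep[worst], "reason": "vif", "value": float(vifs[worst])})
        keep.pop(worst)
    while len(keep) >= 2:
        corr = df[keep].corr().abs().to_numpy()
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.argmax(corr), corr.shape)
        if corr[i, j] < corr_threshold:
            break
        mean_abs = corr.sum(axis=0) / (len(keep) - 1)
        # drop the pair member with the larger mean |r|; ties keep input order
        drop = j if mean_abs[j] >= mean_abs[i] else i
        if mean_abs[i] == mean_abs[j]:
            drop = max(i, j)
        trail.append(
            {"variable": keep[drop], "reason": "pairwise_corr", "value": float(corr[i, j])}
        )
        keep.pop(drop)
    return keep, trail


@dataclass
class SelectionResult:
    """Exhaustive-OLS model set with AICc, Akaike weights and importances."""

    models: pd.DataFrame  # one row per subset: predictors, k, aicc, weight
    importance: pd.DataFrame  # variable, importance, important, effect_sign

    def important_variables(self) -> list[str]:
        return list(self.importance.loc[self.importance["important"], "variable"])


def exhaustive_selection(
    table, response: str, candidates, cutoff: float = 0.8, count_sigma: bool = False
) -> SelectionResult:
    """Fit every predictor subset by OLS and rank by corrected AIC.

    AICc = AIC + 2k(k+1)/(n-k-1) on the RMSE-based AIC; with
    ``count_sigma`` the residual variance is counted as an extra
    parameter (the convention of likelihood-based selection tools).
    Subsets with n - k - 1 <= 0 are skipped.  Importance of a variable is
    the sum of Akaike weights of models containing it; the partial-effect
    sign comes from the full model.
    """
    candidates = list(candidates)
    if len(candidates) > 20:
        raise ValueError("more than 20 candidates: 2^p enumeration refused")
    df = _as_frame(table)[[response] + candidates].dropna()
    y = df[response].to_numpy(float)
    n = len(df)
    rows = []
    for size in range(len(candidates) + 1):
        for subset in combinations(candidates, size):
            k = 1 + len(subset) + (1 if count_sigma else 0)
            if n - k - 1 <= 0:
                rows.append({"predictors": subset, "k": k, "aicc": np.nan, "skipped": True})
                continue
            X = np.column_stack([np.ones(n)] + [df[c].to_numpy(float) for c in subset])
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            rmse = float(np.sqrt(np.mean((X @ beta - y) ** 2)))
            aic = 2.0 * k + n * np.log(rmse**2)
            aicc = aic + 2.0 * k * (k + 1) / (n - k - 1)
            rows.append({"predictors": subset, "k": k, "aicc": aicc, "skipped": False})
    models = pd.DataFrame(rows)
    fitted = models.loc[~models["skipped"]].copy()
    delta = fitted["aicc"] - fitted["aicc"].min()
    w = np.exp(-delta / 2.0)
    fitted["weight"] = w / w.sum()
    models = models.merge(fitted[["weight"]], left_index=True, right_index=True, how="left")

    # full-model coefficient signs for the partial-effect direction
    Xfull = np.column_stack([np.ones(n)] + [df[c].to_numpy(float) for c in candidates])
    beta_full, *_ = np.linalg.lstsq(Xfull, y, rcond=None)
    signs = dict(zip(candidates, np.sign(beta_full[1:]).astype(int)))

    imp_rows = []
    for var in candidates:
        mask = fitted["predictors"].apply(lambda s: var in s)
        imp = float(fitted.loc[mask, "weight"].sum())
        imp_rows.append(
            {
                "variable": var,
                "importance": imp,
                "important": imp >= cutoff,
                "effect_sign": signs[var],
            }
        )
    importance = pd.DataFrame(imp_rows).sort_values(
        "importance", ascending=False, ignore_index=True
    )
    return SelectionResult(models=models, importance=importance)


@dataclass
class PartialRegression:
    """Residual-on-residual regression of the response on one focal
    predictor, holding the other predictors constant (Frisch-Waugh)."""

    focal: str
    x_resid: np.ndarray
    y_resid: np.ndarray
    slope: float
    stderr: float
    conf_int: tuple

    def band(self, x=None, alpha: float = 0.05):
        """(x, fit, lower, upper) confidence band of the partial fit."""
        if x is None:
            x = np.linspace(self.x_resid.min(), self.x_resid.max(), 100)
        res = sm.OLS(self.y_resid, sm.add_constant(self.x_resid)).fit()
        pred = res.get_prediction(sm.add_constant(x))
        ci = pred.conf_int(alpha=alpha)
        return x, pred.predicted_mean, ci[:, 0], ci[:, 1]


def partial_regression(table, response: str, focal: str, others) -> PartialRegression:
    """Partial regression of ``response`` on ``focal`` given ``others``.

    The slope equals the full-model OLS coefficient of the focal
    variable exactly (Frisch-Waugh-Lovell).
    """
    others = list(others)
    if focal in others:
        raise ValueError("focal variable must not appear among the others")
    df = _as_frame(table)[[response, focal] + others].dropna()
    Z = np.column_stack([np.ones(len(df))] + [df[c].to_numpy(float) for c in others])
    if np.linalg.matrix_rank(Z) < Z.shape[1]:
        raise ValueError("the conditioning predictors are collinear (aliased column)")
    y = df[response].to_numpy(float)
    x = df[focal].to_numpy(float)
    proj = lambda v: v - Z @ np.linalg.lstsq(Z, v, rcond=None)[0]
    x_res, y_res = proj(x), proj(y)
    # inference from the full model (correct residual degrees of freedom);
    # its focal coefficient equals the residual-on-residual slope exactly
    full = sm.OLS(y, np.column_stack([Z, x])).fit()
    ci = full.conf_int()
    return PartialRegression(
        focal=focal,
        x_resid=x_res,
        y_resid=y_res,
        slope=float(full.params[-1]),
        stderr=float(full.bse[-1]),
        conf_int=(float(ci[-1, 0]), float(ci[-1, 1])),
    )
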