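"""Metrics, VIF pruning, exhaustive AICc selection, partial regression."""

import numpy as np
import pandas as pd
import pytest

from photocap.assessment import (
    compute_metrics,
    exhaustive_selection,
    partial_regression,
    vif_prune,
)


def test_perfect_prediction_metrics():
    obs = np.array([10.0, 20.0, 30.0])
    m = compute_metrics(obs, obs.copy(), k=3)
    assert (m.r2, m.bias, m.rmse) == (pytest.approx(1.0), 0.0, 0.0)


def test_aic_natural_log_convention():
    """k=2, n=10, RMSE=1 gives AIC=4 (log 1 = 0)."""
    obs = np.arange(10, dtype=float)
    pred = obs + np.array([1.0, -1.0] * 5)
    m = compute_metrics(obs, pred, k=2)
    assert m.rmse == pytest.approx(1.0)
    assert m.aic == pytest.approx(4.0)


def test_zero_variance_raises():
    with pytest.raises(ValueError, match="zero-variance"):
        compute_metrics(np.ones(5), np.arange(5.0), k=1)


def _hadamard_frame(n=8):
    """Mutually orthogonal +/-1 predictors (orthogonal to the intercept too)."""
    H = np.array(
        [
            [1, 1, 1, 1, 1, 1, 1, 1],
            [1, -1, 1, -1, 1, -1, 1, -1],
            [1, 1, -1, -1, 1, 1, -1, -1],
            [1, -1, -1, 1, 1, -1, -1, 1],
        ]
    ).T
    return pd.DataFrame(H[:, 1:].astype(float), columns=["x1", "x2", "x3"])


def test_vif_orthogonal_design_all_retained():
    df = _hadamard_frame()
    kept, trail = vif_prune(df, ["x1", "x2", "x3"])
    assert kept == ["x1", "x2", "x3"] and trail == []


def test_vif_linear_combination_removed_first(rng):
    df = pd.DataFrame(rng.normal(size=(100, 2)), columns=["x1", "x2"])
    df["x3"] = df["x1"] + df["x2"]
    kept, trail = vif_prune(df, ["x1", "x2", "x3"])
    assert trail[0]["variable"] == "x3" and trail[0]["reason"] == "vif"
    assert "x3" not in kept


def test_vif_duplicate_column_one_survives(rng):
    df = pd.DataFrame({"a": rng.normal(size=50)})
    df["b"] = df["a"]
    df["c"] = rng.normal(size=50)
    kept, _ = vif_prune(df, ["a", "b", "c"])
    assert ("a" in kept) ^ ("b" in kept)
    assert "c" in kept


def test_pairwise_correlation_threshold_enforced(rng):
    x = rng.normal(size=300)
    df = pd.DataFrame(
        {"a": x, "b": 0.9 * x + 0.3 * rng.normal(size=300), "c": rng.normal(size=300)}
    )
    kept, trail = vif_prune(df, ["a", "b", "c"])
    corr = df[kept].corr().abs().to_numpy()
    np.fill_diagonal(corr, 0.0)
    assert corr.max() < 0.7


def test_akaike_weights_sum_and_pairwise_ratio(rng):
    n = 120
    df = pd.DataFrame(rng.normal(size=(n, 3)), columns=["x1", "x2", "x3"])
    df["y"] = 2.0 * df["x1"] + rng.normal(size=n)
    sel = exhaustive_selection(df, "y", ["x1", "x2", "x3"])
    fitted = sel.models.dropna(subset=["weight"])
    assert fitted["weight"].sum() == pytest.approx(1.0)
    # weights obey w_i / w_j = exp(-(AICc_i - AICc_j)/2) for every pair
    w = fitted["weight"].to_numpy()
    a = fitted["aicc"].to_numpy()
    ratio = np.log(w[:, None] / w[None, :])
    np.testing.assert_allclose(ratio, -(a[:, None] - a[None, :]) / 2.0, atol=1e-10)


def test_equal_aicc_models_share_weight():
    """Two symmetric single-predictor models tie exactly and split weight."""
    df = _hadamard_frame()
    df["y"] = df["x1"] + df["x2"]
    sel = exhaustive_selection(df, "y", ["x1", "x2"])
    fitted = sel.models.dropna(subset=["weight"])
    w1 = float(fitted.loc[fitted["predictors"].apply(lambda s: s == ("x1",)), "weight"].iloc[0])
    w2 = float(fitted.loc[fitted["predictors"].apply(lambda s: s == ("x2",)), "weight"].iloc[0])
    assert w1 == pytest.approx(w2, rel=1e-12)
    # restricted to the tied pair the weights are 0.5 / 0.5
    assert w1 / (w1 + w2) == pytest.approx(0.5)


def test_importance_of_planted_predictor(rng):
    """One real effect among six candidates: the true variable exceeds the
    0.8 importance cut-off and the noise variables stay below it."""
    n = 200
    df = pd.DataFrame(rng.normal(size=(n, 6)), columns=[f"x{i}" for i in range(6)])
    df["y"] = df["x0"] * 1.0 + rng.normal(scale=0.5, size=n)
    sel = exhaustive_selection(df, "y", list(df.columns[:-1]))
    imp = sel.importance.set_index("variable")["importance"]
    assert imp["x0"] > 0.8
    assert (imp.drop("x0") < 0.8).all()
    assert sel.importance.set_index("variable")["effect_sign"]["x0"] == 1


def test_partial_slope_equals_full_model_coefficient(rng):
    n = 150
    df = pd.DataFrame(rng.normal(size=(n, 4)), columns=["f", "a", "b", "c"])
    df["y"] = 1.5 * df["f"] - 0.7 * df["a"] + rng.normal(size=n)
    pr = partial_regression(df, "y", "f", ["a", "b", "c"])
    import statsmodels.api as sm

    X = sm.add_constant(df[["a", "b", "c", "f"]])
    full = sm.OLS(df["y"], X).fit()
    assert pr.slope == pytest.approx(full.params["f"], abs=1e-10)


def test_partial_regression_orthogonal_case(rng):
    df = _hadamard_frame()
    df["y"] = 2.0 * df["x1"] + df["x2"]
    pr = partial_regression(df, "y", "x1", ["x2"])
    simple = np.polyfit(df["x1"], df["y"], 1)[0]
    assert pr.slope == pytest.approx(simple, abs=1e-10)


def test_partial_regression_rejects_collinear_others(rng):
    df = pd.DataFrame(rng.normal(size=(50, 2)), columns=["f", "a"])
    df["b"] = 2.0 * df["a"]
    df["y"] = rng.normal(size=50)
    with pytest.raises(ValueError, match="collinear"):
        partial_regression(df, "y", "f", ["a", "b"])


def test_partial_slope_coverage(rng):
    """95% interval covers the true coefficient in >= 90% of simulations."""
    hits = 0
    for _ in range(100):
        n = 80
        df = pd.DataFrame(rng.normal(size=(n, 3)), columns=["f", "a", "b"])
        df["y"] = 0.8 * df["f"] + 0.5 * df["a"] + rng.normal(size=n)
        pr = partial_regression(df, "y", "f", ["a", "b"])
        lo, hi = pr.conf_int
        hits += lo <= 0.8 <= hi
    assert hits >= 90
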