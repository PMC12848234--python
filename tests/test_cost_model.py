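"""Dynamic cost model: scenarios, GA calibration, out-of-fold discipline."""

import numpy as np
import pandas as pd
import pytest

import photocap.data_model as dm
from photocap.cost_model import (
    CostModel,
    CVScheme,
    DynamicCostOptimality,
    GAConfig,
    _ga_minimize,
    scenario_covariates,
    site_cost,
)
from photocap.optimality import CostConstant, OptimalityEnv, optimal_vcmax


def test_scenario_covariate_sets():
    assert len(scenario_covariates("top5")) == 5
    assert len(scenario_covariates("edaphic")) == 10
    env_traits = set(scenario_covariates("env_traits"))
    assert set(scenario_covariates("edaphic")) <= env_traits
    assert set(scenario_covariates("top5")) <= env_traits
    assert scenario_covariates("constant") == []


def test_scenario_schema_check():
    with pytest.raises(dm.SchemaError):
        scenario_covariates("top5", ["vpd", "elevation"])


def test_site_cost_constant_and_linear():
    const = CostModel(scenario="constant", beta0=0.053)
    assert site_cost(const, {"soil_ph": 6.0}) == pytest.approx(0.053)
    lin = CostModel(
        scenario="top5", beta0=0.05, betas={"vpd": 1.0}, covariates=["vpd"]
    )
    assert site_cost(lin, {"vpd": 0.01}) == pytest.approx(0.06)


def test_site_cost_missing_covariate_is_schema_error():
    lin = CostModel(scenario="top5", beta0=0.05, betas={"vpd": 1.0}, covariates=["vpd"])
    with pytest.raises(dm.SchemaError):
        site_cost(lin, {"soil_ph": 6.0})


def test_cost_array_matches_generator_truth(optimality_world):
    """Reconstructing c from the generator's own coefficients reproduces the
    latent site costs to machine precision."""
    site, truth = optimality_world
    betas = truth.attrs["cost_beta_std"]
    names = list(betas)
    df = site.df
    mu = df[names].mean()
    sd = df[names].std(ddof=0)
    model = CostModel(
        scenario="edaphic",
        beta0=truth.attrs["cost_beta0"],
        betas=betas,
        covariates=names,
        cov_means=mu.to_dict(),
        cov_sds=sd.to_dict(),
    )
    c = model.cost_array(df)
    c_true = truth.set_index("site_id").loc[df["site_id"], "c_true"].to_numpy()
    # identical up to the generator's feasibility floor
    unclipped = c_true > 0.008
    np.testing.assert_allclose(c[unclipped], c_true[unclipped], atol=1e-12)


def test_constant_scenario_nests_constant_cost_model(optimality_world):
    """beta0 = 0.053 with all betas zero reproduces the constant-cost
    optimality predictions bit-for-bit."""
    site, _ = optimality_world
    df = site.df
    env = OptimalityEnv(
        t_g=df["t_g"].to_numpy(), par=df["par"].to_numpy(), vpd=df["vpd"].to_numpy(),
        ca=df["ca"].to_numpy(), elevation=df["elevation"].to_numpy(),
    )
    ref = optimal_vcmax(env, CostConstant(0.053)).vcmax
    model = CostModel(scenario="edaphic", beta0=0.053, betas={}, covariates=scenario_covariates("edaphic"))
    dyn = optimal_vcmax(env, model.cost_array(df)).vcmax
    assert np.array_equal(ref, dyn)


def test_cv_scheme_partitions_each_repetition():
    cv = CVScheme(n_folds=5, n_repetitions=3, seed=9)
    n = 23
    seen = {}
    for rep, fold, cal, val in cv.iter_folds(n):
        assert len(np.intersect1d(cal, val)) == 0
        seen.setdefault(rep, []).extend(val.tolist())
    for rep, vals in seen.items():
        assert sorted(vals) == list(range(n))


def test_ga_beats_random_and_converges_on_quadratic(rng):
    """On a smooth 3-parameter bowl the annealed GA reaches the optimum."""
    target = np.array([0.07, -0.05, 0.11])
    bounds = np.array([[0.005, 0.3], [-0.2, 0.2], [-0.2, 0.2]])

    def fitness(pop):
        return np.sqrt(((pop - target) ** 2).sum(axis=1))

    params, best = _ga_minimize(fitness, bounds, GAConfig(seed=1), rng)
    np.testing.assert_allclose(params, target, atol=1e-3)


def test_out_of_fold_discipline_and_ensemble(optimality_world):
    """No site is predicted by a model trained on itself, and each site gets
    exactly one prediction per repetition."""
    site, _ = optimality_world
    cv = CVScheme(n_folds=5, n_repetitions=2, seed=3)
    ga = GAConfig(population_size=30, n_generations=60, seed=4)
    res = DynamicCostOptimality(site, "top5").fit(ga, cv)
    assert res.n_failed_folds == 0
    assert len(res.models) == 10
    assert res.oof["vcmax_tg_pred"].notna().all()
    assert len(res.fold_log) == 10


def test_zero_noise_recovery_of_cost_field():
    """With no observation noise and the matching scenario, the ensemble
    recovers the latent cost field almost perfectly."""
    import photocap as pc

    table, truth = pc.generate(
        pc.GeneratorConfig(
            mode="optimality_truth", seed=42, measurements_per_site=1,
            measurement_noise_sd=0.0, optimality_noise_sd=0.0,
        )
    )
    site = pc.prepare_site_table(table)
    res = DynamicCostOptimality(site, "edaphic").fit(
        GAConfig(seed=5), CVScheme(n_folds=5, n_repetitions=2, seed=6)
    )
    merged = res.oof.merge(truth, on="site_id")
    r = np.corrcoef(merged["c_pred"], merged["c_true"])[0, 1]
    assert r > 0.9
    assert res.metrics().r2 > 0.99


def test_requires_site_mean_table(regression_world):
    site, _ = regression_world
    meas = dm.SiteTable(site.df.copy(), level="measurement")
    with pytest.raises(ValueError):
        DynamicCostOptimality(meas, "edaphic")
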