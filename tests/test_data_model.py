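"""Schema, CSV round-trips, concurrent-measurement filter, site means."""

import numpy as np
import pandas as pd
import pytest

import photocap.data_model as dm


def _toy_df(n=5):
    return pd.DataFrame(
        {
            "site_id": [f"S{i}" for i in range(n)],
            "vcmax_tmeas": np.linspace(30, 70, n),
            "t_meas": np.linspace(18, 30, n),
            "t_g": np.linspace(10, 25, n),
            "vpd": 1.0,
            "par": 800.0,
            "ca": 400.0,
            "lma": 90.0,
            "na": 1.8,
        }
    )


def test_round_trip_preserves_values(tmp_path):
    table = dm.SiteTable(_toy_df())
    path = tmp_path / "t.csv"
    dm.write_site_table(table, path)
    back = dm.read_site_table(path)
    for col in table.df.columns:
        if col == "site_id":
            assert list(back.df[col]) == list(table.df[col])
        else:
            np.testing.assert_allclose(back.df[col], table.df[col], atol=1e-9)


def test_missing_mandatory_column_is_schema_error(tmp_path):
    df = _toy_df().drop(columns=["vcmax_tmeas"])
    path = tmp_path / "bad.csv"
    df.to_csv(path, index=False)
    with pytest.raises(dm.SchemaError):
        dm.read_site_table(path)


def test_non_numeric_cell_names_row_and_column(tmp_path):
    df = _toy_df()
    df["vpd"] = df["vpd"].astype(object)
    df.loc[2, "vpd"] = "oops"
    path = tmp_path / "bad.csv"
    df.to_csv(path, index=False)
    with pytest.raises(dm.ParseError, match="vpd"):
        dm.read_site_table(path)


def test_schema_config_renames_columns(tmp_path):
    df = _toy_df().rename(columns={"vcmax_tmeas": "Vcmax", "t_meas": "Tleaf"})
    path = tmp_path / "renamed.csv"
    df.to_csv(path, index=False)
    table = dm.read_site_table(
        path, {"columns": {"Vcmax": "vcmax_tmeas", "Tleaf": "t_meas"}}
    )
    assert "vcmax_tmeas" in table.df.columns


def test_filter_concurrent_counts():
    df = _toy_df()
    df.loc[[1, 3], "t_meas"] = np.nan
    table = dm.SiteTable(df)
    out, report = dm.filter_concurrent(table)
    assert (report.records_in, report.records_kept) == (5, 3)
    # surviving rows are unaltered
    pd.testing.assert_frame_equal(
        out.df.reset_index(drop=True),
        df.loc[df["t_meas"].notna()].reset_index(drop=True),
    )


def test_filter_requires_traits_with_missing_na_column():
    df = _toy_df().drop(columns=["na"])
    with pytest.warns(UserWarning, match="empty"):
        out, report = dm.filter_concurrent(dm.SiteTable(df), require_traits=True)
    assert report.records_kept == 0


def test_filter_matches_bruteforce_on_random_missingness(rng):
    df = _toy_df(200)
    miss_t = rng.random(200) < 0.3
    miss_na = rng.random(200) < 0.2
    df.loc[miss_t, "t_meas"] = np.nan
    df.loc[miss_na, "na"] = np.nan
    out, report = dm.filter_concurrent(dm.SiteTable(df), require_traits=True)
    assert report.records_kept == int((~miss_t & ~miss_na).sum())


def test_aggregate_site_means_and_idempotence():
    df = _toy_df(4)
    df["site_id"] = ["A", "A", "B", "C"]
    table = dm.SiteTable(df)
    site = dm.aggregate_site_means(table)
    assert site.level == "site-mean"
    assert len(site) == 3
    a = site.df.set_index("site_id").loc["A"]
    assert a["vcmax_tmeas"] == pytest.approx(df.loc[:1, "vcmax_tmeas"].mean())
    # single-measurement sites unchanged
    c = site.df.set_index("site_id").loc["C"]
    assert c["vcmax_tmeas"] == pytest.approx(df.loc[3, "vcmax_tmeas"])
    again = dm.aggregate_site_means(site)
    pd.testing.assert_frame_equal(site.df, again.df)


def test_site_mean_table_rejects_duplicate_sites():
    df = _toy_df(2)
    df["site_id"] = ["A", "A"]
    with pytest.raises(dm.SchemaError):
        dm.SiteTable(df, level="site-mean")


def test_invariant_validation_rejects_negative_vcmax():
    df = _toy_df()
    df.loc[0, "vcmax_tmeas"] = -5.0
    with pytest.raises(ValueError, match="vcmax_tmeas"):
        dm.SiteTable(df)


def test_site_means_converge_to_generator_truth():
    """Many replicate measurements per site average toward the generator's
    site-level value."""
    import photocap as pc

    table, truth = pc.generate(
        pc.GeneratorConfig(
            n_sites=20, measurements_per_site=100, seed=5, measurement_noise_sd=0.05
        )
    )
    site = pc.prepare_site_table(table)
    merged = site.df.merge(truth, on="site_id")
    # mean of multiplicative-noise replicates ~ vcmax_25_site within MC error
    rel = merged["vcmax_25"] / merged["vcmax_25_site"] - 1.0
    assert np.abs(rel).max() < 0.05 / np.sqrt(100) * 4
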