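"""Site-level schema for leaf gas-exchange Vcmax data and its covariates.

A :class:`SiteTable` wraps a pandas DataFrame with canonical column names:
one row per gas-exchange measurement (``measurement`` level) or per site
(``site-mean`` level).  Columns split into six climate variables, ten
edaphic variables and two leaf traits, plus the response (Vcmax at the
leaf measurement temperature) and identification metadata.

Missing values are empty cells in CSV; any sentinel code (e.g. -9999)
must be declared in the schema config, never guessed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SiteTable",
    "SchemaError",
    "ParseError",
    "FilterReport",
    "read_site_table",
    "write_site_table",
    "filter_concurrent",
    "aggregate_site_means",
    "CLIMATE_VARS",
    "EDAPHIC_VARS",
    "TRAIT_VARS",
    "NUMERIC_VARS",
]

CLIMATE_VARS = ["t_g", "vpd", "par", "ca", "elevation", "precipitation"]
EDAPHIC_VARS = [
    "soil_ph",
    "soil_c",
    "soil_n",
    "soil_cn",
    "alpha_pt",
    "cec",
    "silt",
    "clay",
    "sand",
    "bulk_density",
]
TRAIT_VARS = ["lma", "na"]

#: all numeric columns, in canonical order
NUMERIC_VARS = (
    ["vcmax_tmeas", "t_meas", "vcmax_tg", "vcmax_25"]
    + CLIMATE_VARS
    + EDAPHIC_VARS
    + TRAIT_VARS
)
META_VARS = ["site_id", "latitude", "longitude", "species"]
MANDATORY = ["site_id", "vcmax_tmeas", "t_meas"]

#: units documented for the CSV header (informational)
UNITS = {
    "vcmax_tmeas": "umol m-2 s-1",
    "vcmax_tg": "umol m-2 s-1",
    "vcmax_25": "umol m-2 s-1",
    "t_meas": "degC",
    "t_g": "degC",
    "vpd": "kPa",
    "par": "umol m-2 s-1",
    "ca": "ppm",
    "elevation": "m",
    "precipitation": "mm",
    "soil_ph": "-",
    "soil_c": "g kg-1",
    "soil_n": "g kg-1",
    "soil_cn": "-",
    "alpha_pt": "-",
    "cec": "cmol kg-1",
    "silt": "%",
    "clay": "%",
    "sand": "%",
    "bulk_density": "g cm-3",
    "lma": "g m-2",
    "na": "g m-2",
}


class SchemaError(ValueError):
    """Raised when a table lacks mandatory columns or maps unknown names."""


class ParseError(ValueError):
    """Raised when a numeric cell cannot be parsed; names row and column."""


@dataclass
class SiteTable:
    """Ordered collection of site measurements plus provenance metadata.

    Parameters
    ----------
    df : pandas.DataFrame
        Canonical-named columns; numeric columns are float with NaN for
        missing values.
    level : str
        ``"measurement"`` or ``"site-mean"``.
    provenance : dict
        Free-form record of source file and processing flags.
    """

    df: pd.DataFrame
    level: str = "measurement"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.level not in ("measurement", "site-mean"):
            raise ValueError(f"unknown aggregation level {self.level!r}")
        if "site_id" not in self.df.columns:
            raise SchemaError("site_id column is mandatory")
        if self.df["site_id"].astype(str).str.len().eq(0).any():
            raise SchemaError("site_id must be non-empty")
        if self.level == "site-mean" and self.df["site_id"].duplicated().any():
            raise SchemaError("site-mean table must have one row per site_id")
        self._validate_invariants()

    def _validate_invariants(self) -> None:
        df = self.df

        def bad(col, mask):
            idx = df.index[mask.fillna(False)]
            if len(idx):
                raise ValueError(f"invariant violated for {col} at rows {list(idx[:5])}")

        if "vcmax_tmeas" in df:
            bad("vcmax_tmeas > 0", df["vcmax_tmeas"] <= 0)
        if "vpd" in df:
            bad("vpd >= 0", df["vpd"] < 0)
        if "par" in df:
            bad("par >= 0", df["par"] < 0)
        if "ca" in df:
            bad("ca > 0", df["ca"] <= 0)
        if "soil_ph" in df:
            bad("soil_ph in [2, 11]", (df["soil_ph"] < 2) | (df["soil_ph"] > 11))
        if all(c in df for c in ("silt", "clay", "sand")):
            total = df["silt"] + df["clay"] + df["sand"]
            # tolerance for source rounding in texture fractions
            bad("texture sum in [95, 105]", (total < 95) | (total > 105))

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_sites(self) -> int:
        return self.df["site_id"].nunique()

    def copy(self) -> "SiteTable":
        return SiteTable(self.df.copy(), self.level, dict(self.provenance))


@dataclass(frozen=True)
class FilterReport:
    records_in: int
    records_kept: int
    sites_in: int
    sites_kept: int


def _load_schema_config(schema_config):
    """Schema config: YAML mapping with optional keys ``columns`` (user name
    -> canonical name), ``sentinel`` (value to treat as missing), ``units``."""
    if schema_config is None:
        return {}, None
    if isinstance(schema_config, dict):
        cfg = schema_config
    else:
        with open(schema_config) as fh:
            cfg = yaml.safe_load(fh) or {}
    mapping = cfg.get("columns", {}) or {}
    unknown = set(mapping.values()) - set(NUMERIC_VARS + META_VARS)
    if unknown:
        raise SchemaError(f"schema maps to unknown canonical columns: {sorted(unknown)}")
    units = cfg.get("units", {}) or {}
    for canon, unit in units.items():
        if canon in UNITS and unit != UNITS[canon]:
            raise SchemaError(
                f"unit mismatch for {canon}: declared {unit!r}, expected {UNITS[canon]!r}"
            )
    return mapping, cfg.get("sentinel")


def read_site_table(path, schema_config=None) -> SiteTable:
    """Read a measurement-level CSV into a :class:`SiteTable`.

    ``schema_config`` (dict or YAML path) may rename user columns to the
    canonical schema and declare a missing-value sentinel.
    """
    mapping, sentinel = _load_schema_config(schema_config)
    raw = pd.read_csv(path, dtype=str, keep_default_na=True)
    raw = raw.rename(columns=mapping)
    missing = [c for c in MANDATORY if c not in raw.columns]
    if missing:
        raise SchemaError(f"mandatory columns missing: {missing}")

    df = pd.DataFrame(index=raw.index)
    for col in META_VARS:
        if col in raw.columns:
            df[col] = raw[col]
    for col in NUMERIC_VARS:
        if col not in raw.columns:
            continue
        series = raw[col]
        parsed = pd.to_numeric(series, errors="coerce")
        bad = parsed.isna() & series.notna() & (series.str.strip() != "")
        if bad.any():
            row = int(df.index[bad][0])
            raise ParseError(
                f"non-numeric value {series[bad].iloc[0]!r} in column {col!r}, row {row}"
            )
        if sentinel is not None:
            parsed = parsed.mask(parsed == sentinel)
        df[col] = parsed
    return SiteTable(df, level="measurement", provenance={"source": str(path)})


def write_site_table(table: SiteTable, path) -> None:
    """Write the canonical CSV (full float precision, empty cells for NaN)."""
    table.df.to_csv(path, index=False, float_format="%.12g")


def filter_concurrent(
    table: SiteTable, require_traits: bool = False, require_edaphic: bool = False
) -> tuple[SiteTable, FilterReport]:
    """Keep only records with a concurrent leaf-temperature measurement.

    With ``require_traits``, records must also carry both leaf traits
    (LMA and area-based leaf N); with ``require_edaphic``, all ten edaphic
    covariates.  Surviving rows are returned unaltered.
    """
    if table.level != "measurement":
        raise ValueError("filter_concurrent expects a measurement-level table")
    df = table.df
    keep = df["t_meas"].notna() & df["vcmax_tmeas"].notna()
    if require_traits:
        for col in TRAIT_VARS:
            keep &= df[col].notna() if col in df else False
    if require_edaphic:
        for col in EDAPHIC_VARS:
            keep &= df[col].notna() if col in df else False
    out = df.loc[keep].copy()
    report = FilterReport(
        records_in=len(df),
        records_kept=len(out),
        sites_in=df["site_id"].nunique(),
        sites_kept=out["site_id"].nunique() if len(out) else 0,
    )
    if report.records_kept == 0:
        warnings.warn("filter_concurrent produced an empty table", UserWarning)
    prov = dict(table.provenance)
    prov["filter"] = {"require_traits": require_traits, "require_edaphic": require_edaphic}
    return SiteTable(out.reset_index(drop=True), "measurement", prov), report


def aggregate_site_means(table: SiteTable) -> SiteTable:
    """Average all measurements of each site (unweighted arithmetic mean).

    Idempotent on site-mean tables.  Metadata columns take their first
    non-missing value per site; species is dropped (multi-species sites
    are pooled).
    """
    df = table.df
    grouped = df.groupby("site_id", sort=False)
    num_cols = [c for c in NUMERIC_VARS if c in df.columns]
    out = grouped[num_cols].mean()
    for col in ("latitude", "longitude"):
        if col in df.columns:
            out[col] = grouped[col].first()
    out = out.reset_index()
    prov = dict(table.provenance)
    prov["aggregated"] = True
    return SiteTable(out, "site-mean", prov)
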