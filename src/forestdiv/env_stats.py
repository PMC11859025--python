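"""Subplot-level species richness vs soil environment.

Links the census to a subplot-level environment table (pH, soil organic
matter %, water content %, total N/P/K in g/kg) via ordinary least squares
and Pearson correlation — the plot-scale analog of richness-environment
scatter analyses. No spatial autocorrelation correction is applied; see
the methods note for the resulting caveat on p-values.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import CensusTable

ENV_VARIABLES = ["pH", "SOM", "WC", "TN", "TP", "TK"]


def subplot_richness(census: CensusTable) -> pd.Series:
    """Distinct species per subplot, indexed by flat subplot index
    (row-major from the SW corner); empty subplots count 0."""
    sub = census.subplot_of_stems()
    rich = (
        pd.DataFrame({"subplot": sub, "species": census.data["species"]})
        .groupby("subplot")["species"]
        .nunique()
    )
    return rich.reindex(range(census.window.n_subplots), fill_value=0).rename(
        "richness"
    )


def validate_env_table(df: pd.DataFrame) -> None:
    if "subplot" not in df.columns:
        raise ValueError("env table needs a 'subplot' index column")
    vals = df.drop(columns=["subplot"])
    if not np.isfinite(vals.to_numpy(float)).all():
        raise ValueError("env table contains non-finite values")
    if "pH" in df.columns and not df["pH"].between(0, 14, inclusive="neither").all():
        raise ValueError("pH outside (0, 14)")


def read_env_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    validate_env_table(df)
    return df


def write_env_table(df: pd.DataFrame, path) -> None:
    validate_env_table(df)
    df.to_csv(path, index=False)


class RegressionResult(NamedTuple):
    pearson_r: float
    slope: float
    intercept: float
    p_value: float
    n: int


def richness_env_regression(y, x) -> RegressionResult:
    """OLS line and Pearson correlation between two subplot series.

    Conventionally ``y`` is subplot richness and ``x`` an environmental
    variable; the Pearson r and its two-sided p are orientation-free.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.size != x.size or y.size < 3:
        raise ValueError("need >= 3 paired observations")
    if np.std(y) == 0 or np.std(x) == 0:
        raise ValueError("zero variance in one of the variables")
    fit = stats.linregress(x, y)
    return RegressionResult(
        pearson_r=float(fit.rvalue), slope=float(fit.slope),
        intercept=float(fit.intercept), p_value=float(fit.pvalue), n=int(y.size),
    )


def richness_env_summary(census: CensusTable, env: pd.DataFrame) -> pd.DataFrame:
    """Regression of richness on every environment variable present."""
    rich = subplot_richness(census)
    env = env.set_index("subplot") if "subplot" in env.columns else env
    rows = {}
    for var in env.columns:
        x = env[var].reindex(rich.index)
        res = richness_env_regression(rich.to_numpy(), x.to_numpy())
        rows[var] = res._asdict()
    return pd.DataFrame(rows).T
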