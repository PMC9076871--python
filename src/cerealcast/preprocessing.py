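"""Standardized, detrended anomalies from raw yields and climate series.

Yields: per-province production/area -> regional mean ton/ha -> linear
detrend over years (removes the technological trend) -> divide by the
residual SD.  Climate: the same detrend-and-standardize applied per calendar
month across years (the interannual axis), independently for each region and
variable.  Standardization uses the population SD (divide by n); the choice
cancels in every correlation-based metric downstream and is recorded in the
provenance of each series.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._calendar import days_in_month
from .containers import MonthlyClimatePanel, YieldAnomalySeries
from .errors import CalendarError, CoverageError, DegenerateInputError


def compute_regional_yield(
    records: pd.DataFrame, region: str, cereal: str | None = None
) -> pd.Series:
    """Annual regional yield [ton/ha]: unweighted mean of province production/area.

    ``records`` columns: province, region, year, production_ton, area_ha
    (and cereal, if ``cereal`` is given).  Every province must report every
    year — missing years raise rather than being silently filled.
    """
    sub = records[records["region"] == region]
    if cereal is not None:
        sub = sub[sub["cereal"] == cereal]
    if sub.empty:
        raise CoverageError(f"no yield records for region={region!r} cereal={cereal!r}")

    bad = sub[sub["area_ha"] <= 0]
    if not bad.empty:
        row = bad.iloc[0]
        raise ValueError(
            f"non-positive area for province {row['province']!r} in year {int(row['year'])}"
        )

    sub = sub.assign(yield_ton_ha=sub["production_ton"] / sub["area_ha"])
    years = sorted(sub["year"].unique())
    provinces = sorted(sub["province"].unique())
    counts = sub.groupby("province")["year"].nunique()
    incomplete = counts[counts < len(years)]
    if not incomplete.empty:
        prov = incomplete.index[0]
        missing = sorted(set(years) - set(sub[sub["province"] == prov]["year"]))
        raise CoverageError(f"province {prov!r} missing years {missing}")

    regional = sub.groupby("year")["yield_ton_ha"].mean().sort_index()
    regional.name = "yield_ton_ha"
    regional.index = regional.index.astype(int)
    return regional


def detrend_and_standardize(
    values: np.ndarray | pd.Series, years: np.ndarray | None = None
) -> tuple[np.ndarray, dict]:
    """OLS-detrend a series against year and divide residuals by their SD.

    Returns (anomalies, provenance); provenance records the trend slope and
    intercept and the (population) SD divided out, so the transform is
    invertible.  A series whose residuals are all zero (constant, or an
    exact linear ramp) is degenerate and raises.
    """
    if isinstance(values, pd.Series):
        if years is None:
            years = values.index.to_numpy()
        values = values.to_numpy()
    values = np.asarray(values, dtype=float)
    if years is None:
        years = np.arange(len(values))
    years = np.asarray(years, dtype=float)
    if len(values) < 3:
        raise ValueError(f"need at least 3 points to detrend, got {len(values)}")

    slope, intercept = np.polyfit(years, values, 1)
    residuals = values - (intercept + slope * years)
    sd = float(np.std(residuals))  # population convention (divide by n)
    if sd < 1e-12:
        raise DegenerateInputError(
            "series is constant or an exact linear trend; standardized anomalies undefined"
        )
    anomalies = residuals / sd
    provenance = {
        "slope": float(slope),
        "intercept": float(intercept),
        "sd": sd,
        "sd_convention": "population",
        "raw_values": [float(v) for v in values],
    }
    return anomalies, provenance


def yield_anomaly_series(
    records: pd.DataFrame, region: str, cereal: str
) -> YieldAnomalySeries:
    """Standardized detrended yield anomalies for one (region, cereal).

    Detrending is applied after regional averaging (province series are
    averaged first, then the single regional series is detrended); the order
    is recorded in the provenance.
    """
    regional = compute_regional_yield(records, region, cereal)
    anomalies, provenance = detrend_and_standardize(regional)
    provenance["detrend_order"] = "after_regional_mean"
    return YieldAnomalySeries(
        region=region,
        cereal=cereal,
        years=regional.index.to_numpy(),
        anomalies=anomalies,
        provenance=provenance,
    )


def standardize_monthly_anomalies(panel: MonthlyClimatePanel) -> MonthlyClimatePanel:
    """Add a standardized-anomaly layer to a climate panel.

    For each (region, variable, calendar month), the series of values across
    years is detrended against year and divided by the population SD of the
    residuals — the interannual standardization.  Degenerate cells report
    the offending calendar month.
    """
    data = panel.data.copy()
    data["anomaly"] = np.nan
    for (region, var, month), idx in data.groupby(["region", "variable", "month"]).groups.items():
        block = data.loc[idx].sort_values("year")
        if len(block) < 3:
            raise ValueError(
                f"need >= 3 years for ({region}, {var}, month {month}), got {len(block)}"
            )
        try:
            anoms, _ = detrend_and_standardize(
                block["value"].to_numpy(), block["year"].to_numpy()
            )
        except DegenerateInputError as exc:
            raise DegenerateInputError(
                f"degenerate climate series for ({region}, {var}) in calendar month {month}: {exc}"
            ) from exc
        data.loc[block.index, "anomaly"] = anoms
    return MonthlyClimatePanel(data)


def aggregate_daily_to_monthly(daily: pd.DataFrame) -> pd.DataFrame:
    """Monthly PR (sum of daily totals, mm), TX/TN (means of daily extrema, K).

    ``daily`` columns: region, date (parseable), pr_mm, tx_k, tn_k.  Every
    aggregated month must be complete — leap Februaries need 29 days.
    """
    d = daily.copy()
    d["date"] = pd.to_datetime(d["date"])
    d["year"] = d["date"].dt.year
    d["month"] = d["date"].dt.month

    for (region, year, month), block in d.groupby(["region", "year", "month"]):
        expected = days_in_month(int(year), int(month))
        got = block["date"].dt.day.nunique()
        if got != expected:
            raise CalendarError(
                f"region {region!r} {int(year)}-{int(month):02d}: "
                f"{got} distinct days provided, {expected} required"
            )

    agg = d.groupby(["region", "year", "month"]).agg(
        PR=("pr_mm", "sum"), TX=("tx_k", "mean"), TN=("tn_k", "mean")
    )
    out = agg.reset_index().melt(
        id_vars=["region", "year", "month"], var_name="variable", value_name="value"
    )
    return out[["region", "variable", "year", "month", "value"]].sort_values(
        ["region", "variable", "year", "month"], ignore_index=True
    )
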