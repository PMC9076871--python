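"""Lead- and calendar-month-dependent mean correction of ensemble forecasts.

Coupled forecast systems drift: their climatology departs from the
observational one as lead time grows.  The correction aligns the two by
matching multiannual means per (issue month m, lead lt) against the
observed climatology of the verification month m_v = m + lt (circular over
12 months):

    PR' = alpha_PR(m, lt) * PR      alpha_PR = mean_obs_PR(m_v) / mean_fc_PR(m, lt)
    TX' = alpha_TX(m, lt) + TX      alpha_TX = mean_obs_TX(m_v) - mean_fc_TX(m, lt)
    TN' = alpha_TN(m, lt) + TN      alpha_TN likewise

Forecast means are taken over both calibration years and ensemble members.
Multiplicative correction keeps precipitation non-negative; additive
correction leaves the ensemble spread untouched.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from ._calendar import days_in_month, month_before, verification_month, verification_year
from .containers import CorrectionFactors, EnsembleForecastSet, MonthlyClimatePanel
from .errors import CoverageError, DegenerateInputError

#: below this climatological precipitation [mm] the ratio correction is refused
PR_MEAN_FLOOR_MM = 1e-6

_CELL = ["region", "variable", "issue_month", "lead"]


def convert_precip_rate_to_total(
    rate: float | np.ndarray, year: int, month: int
) -> float | np.ndarray:
    """Monthly-mean precipitation rate [m s^-1] -> monthly accumulation [mm].

    mm = rate * 86400 s/day * days_in_month(year, month) * 1000 mm/m,
    leap-aware.
    """
    rate = np.asarray(rate, dtype=float)
    if np.any(rate < 0):
        raise ValueError("negative precipitation rate")
    out = rate * 86400.0 * days_in_month(year, month) * 1000.0
    return float(out) if out.ndim == 0 else out


def compute_correction_factors(
    forecasts: EnsembleForecastSet,
    observations: MonthlyClimatePanel,
    years: list[int] | None = None,
) -> CorrectionFactors:
    """Estimate the per-(region, variable, issue month, lead) factors.

    ``years`` restricts the calibration period (issue years used); the
    default is every issue year in the forecast set.  Observations must
    cover every verification month/year the grid implies, in final units
    (PR already accumulated to mm).
    """
    fc = forecasts.with_verification()
    if years is not None:
        fc = fc[fc["issue_year"].isin(years)]
        if fc.empty:
            raise CoverageError("no forecast data in requested calibration years")

    fc_mean = fc.groupby(_CELL, as_index=False).agg(fc_mean=("value", "mean"))

    # observed climatology over exactly the verification (year, month) pairs
    # each cell covers
    pairs = fc[_CELL + ["verif_year", "verif_month"]].drop_duplicates()
    obs = observations.data.rename(columns={"year": "verif_year", "month": "verif_month"})
    merged = pairs.merge(
        obs[["region", "variable", "verif_year", "verif_month", "value"]],
        on=["region", "variable", "verif_year", "verif_month"],
        how="left",
    )
    if merged["value"].isna().any():
        miss = merged[merged["value"].isna()].iloc[0]
        raise CoverageError(
            "observations missing "
            f"({miss['region']}, {miss['variable']}, {int(miss['verif_year'])}, "
            f"{int(miss['verif_month'])}) needed for correction"
        )
    obs_mean = merged.groupby(_CELL, as_index=False).agg(obs_mean=("value", "mean"))

    table = fc_mean.merge(obs_mean, on=_CELL)
    is_pr = table["variable"] == "PR"
    degenerate = is_pr & (table["fc_mean"] <= PR_MEAN_FLOOR_MM)
    if degenerate.any():
        row = table[degenerate].iloc[0]
        raise DegenerateInputError(
            f"forecast climatological precipitation ~0 at ({row['region']}, "
            f"m={int(row['issue_month'])}, lt={int(row['lead'])}); ratio correction undefined"
        )
    table["alpha"] = np.where(
        is_pr, table["obs_mean"] / table["fc_mean"], table["obs_mean"] - table["fc_mean"]
    )

    mv = (table["issue_month"].to_numpy(int) + table["lead"].to_numpy(int) - 1) % 12 + 1
    obs_clim = (
        table.assign(month=mv)[["region", "variable", "month", "obs_mean"]]
        .rename(columns={"obs_mean": "mean"})
        .drop_duplicates(subset=["region", "variable", "month"])
        .sort_values(["region", "variable", "month"], ignore_index=True)
    )
    return CorrectionFactors(
        table=table[_CELL + ["alpha"]].sort_values(_CELL, ignore_index=True),
        obs_climatology=obs_clim,
    )


def apply_correction(
    forecasts: EnsembleForecastSet, factors: CorrectionFactors
) -> EnsembleForecastSet:
    """Apply the factors member-wise; the raw set is left unmodified."""
    d = forecasts.data.merge(factors.table, on=_CELL, how="left")
    if d["alpha"].isna().any():
        miss = d[d["alpha"].isna()][_CELL].drop_duplicates()
        raise CoverageError(f"no correction factor for cells:\n{miss.head().to_string()}")
    is_pr = (d["variable"] == "PR").to_numpy()
    value = d["value"].to_numpy(dtype=float)
    alpha = d["alpha"].to_numpy(dtype=float)
    d["value"] = np.where(is_pr, alpha * value, alpha + value)
    return EnsembleForecastSet(d.drop(columns=["alpha"]), corrected=True)


def skill_matrix(
    observations: MonthlyClimatePanel,
    forecasts: EnsembleForecastSet | None = None,
    persistence: bool = False,
    leads: range = range(0, 7),
) -> pd.DataFrame:
    """Pearson R by (region, variable, verification month, lead), with p < 0.05 flags.

    Dynamical mode correlates the ensemble-mean forecast against the
    observations of the verification month.  Persistence mode correlates
    observations of the verification month against the observation known
    when the forecast was issued: the month before the issue month (for
    lead lt and verification month m_v, that is month m_v - lt - 1).
    Cells with fewer than 3 overlapping years are marked missing (NaN R).
    """
    if persistence == (forecasts is not None):
        raise ValueError("provide exactly one of forecasts= or persistence=True")

    obs_lookup = observations.value_lookup()
    rows = []
    if forecasts is not None:
        em = forecasts.ensemble_mean()
        for (region, var, im, lt), block in em.groupby(
            ["region", "variable", "issue_month", "lead"]
        ):
            mv = verification_month(int(im), int(lt))
            x, y = [], []
            for iy, val in zip(block["issue_year"], block["value"]):
                yv = verification_year(int(iy), int(im), int(lt))
                key = (region, var, yv, mv)
                if key in obs_lookup:
                    x.append(val)
                    y.append(obs_lookup[key])
            rows.append(_skill_row(region, var, mv, int(lt), x, y))
    else:
        regions = observations.regions()
        variables = sorted(observations.data["variable"].unique())
        years = observations.years()
        for region in regions:
            for var in variables:
                for mv in range(1, 13):
                    for lt in leads:
                        im = (mv - lt - 1) % 12 + 1
                        known = month_before(im)
                        x, y = [], []
                        for yv in years:
                            iy = yv - (im + lt - 1) // 12
                            ky = iy - 1 if im == 1 else iy
                            k_obs = (region, var, yv, mv)
                            k_known = (region, var, ky, known)
                            if k_obs in obs_lookup and k_known in obs_lookup:
                                x.append(obs_lookup[k_known])
                                y.append(obs_lookup[k_obs])
                        rows.append(_skill_row(region, var, mv, lt, x, y))
    return pd.DataFrame(rows)


def _skill_row(region, var, mv, lt, x, y) -> dict:
    if len(x) < 3:
        return {
            "region": region, "variable": var, "verif_month": mv, "lead": lt,
            "n": len(x), "R": np.nan, "p_value": np.nan, "significant": False,
        }
    r, p = stats.pearsonr(np.asarray(x, float), np.asarray(y, float))
    return {
        "region": region, "variable": var, "verif_month": mv, "lead": lt,
        "n": len(x), "R": float(r), "p_value": float(p), "significant": bool(p < 0.05),
    }
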