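"""Assemble per-issue-month predictor vectors and forecast yield anomalies.

For an issue month M (forecasts issued on the 1st of the month, January
through June), a model term in month T is

* observed (OBS) if T is strictly before M in season order (Oct < Nov < ...
  < Jun) — the reanalysis anomaly is used;
* forecast otherwise.  The dynamical system (DYN) supplies the corrected
  ensemble anomaly at lead = position(T) - position(M) (lead 0 is the issue
  month itself, whose anomaly is only known once the month ends).  The
  persistence baseline (PERSIST) assigns every future term the observed
  anomaly of month M - 1, the last month known at issue time.

The BENCHMARK system sources every term from observations regardless of
issue month — the regression's ceiling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._calendar import ISSUE_MONTHS, MAX_LEAD, climate_year, month_before, season_position
from .containers import EnsembleForecastSet, MonthlyClimatePanel, RegressionModel, term_name
from .errors import CoverageError
from .preprocessing import detrend_and_standardize

SYSTEMS = ("DYN", "PERSIST", "BENCHMARK")

_CELL = ["region", "variable", "issue_month", "lead"]


def standardize_forecast_anomalies(
    forecasts: EnsembleForecastSet,
    method: str = "self",
    observations: MonthlyClimatePanel | None = None,
) -> pd.DataFrame:
    """Standardized anomalies of (corrected) forecasts, member-wise.

    method="self" (default): per (region, variable, issue month, lead), the
    interannual trend and population SD of the *ensemble-mean* series are
    computed across issue years and applied to every member.  This mirrors
    the observational standardization on the forecast's own climatology, so
    residual system biases cannot leak into the anomalies.

    method="obs": the trend/SD of the observed series of the verification
    calendar month are applied instead (requires ``observations``).

    Returns columns: region, variable, issue_year, issue_month, lead,
    member, anomaly.
    """
    fc = forecasts.with_verification()

    if method == "self":
        em = fc.groupby(_CELL + ["issue_year"], as_index=False)["value"].mean()
        params = []
        for key, block in em.groupby(_CELL):
            _, prov = detrend_and_standardize(
                block["value"].to_numpy(), block["issue_year"].to_numpy(float)
            )
            params.append(dict(zip(_CELL, key)) | {
                "slope": prov["slope"], "intercept": prov["intercept"], "sd": prov["sd"],
            })
        out = fc.merge(pd.DataFrame(params), on=_CELL, how="left")
        trend = out["intercept"] + out["slope"] * out["issue_year"]
    elif method == "obs":
        if observations is None:
            raise ValueError("method='obs' requires an observations panel")
        params = []
        for (region, var, mv), block in observations.data.groupby(["region", "variable", "month"]):
            block = block.sort_values("year")
            _, prov = detrend_and_standardize(
                block["value"].to_numpy(), block["year"].to_numpy(float)
            )
            params.append({
                "region": region, "variable": var, "verif_month": mv,
                "slope": prov["slope"], "intercept": prov["intercept"], "sd": prov["sd"],
            })
        out = fc.merge(pd.DataFrame(params), on=["region", "variable", "verif_month"], how="left")
        trend = out["intercept"] + out["slope"] * out["verif_year"]
    else:
        raise ValueError(f"unknown standardization method {method!r}")

    if out["sd"].isna().any():
        miss = out[out["sd"].isna()][_CELL].drop_duplicates()
        raise CoverageError(f"no standardization parameters for cells:\n{miss.head().to_string()}")
    out["anomaly"] = (out["value"] - trend) / out["sd"]
    return out[["region", "variable", "issue_year", "issue_month", "lead", "member", "anomaly"]]


def dyn_anomaly_lookup(dyn_anoms: pd.DataFrame) -> dict:
    """(region, variable, issue_month, issue_year, lead) -> member-ordered anomaly array."""
    d = dyn_anoms.sort_values("member")
    out: dict = {}
    for key, block in d.groupby(["region", "variable", "issue_month", "issue_year", "lead"]):
        region, var, im, iy, lt = key
        out[(region, var, int(im), int(iy), int(lt))] = block["anomaly"].to_numpy()
    return out


@dataclass
class AssembledPredictors:
    """Predictor vector(s) for one (model, issue month, harvest year).

    ``values`` has shape (n_terms,) for deterministic sources or
    (n_terms, n_members) when dynamical members are propagated; ``sources``
    tags each term OBS / DYN / PERSIST and ``leads`` gives the lead used
    for DYN terms (None otherwise).
    """

    model: RegressionModel
    issue_month: int
    year: int
    values: np.ndarray
    sources: list[str]
    leads: list[int | None]


def _obs_anomaly(obs_lookup: dict, region: str, var: str, harvest_year: int, month: int) -> float:
    key = (region, var, climate_year(harvest_year, month), month)
    if key not in obs_lookup:
        raise CoverageError(f"observed anomaly missing for {key}")
    return float(obs_lookup[key])


def assemble_predictors(
    model: RegressionModel,
    issue_month: int,
    year: int,
    obs_lookup: dict,
    mode: str,
    dyn_anoms: pd.DataFrame | dict | None = None,
    ensemble: str = "mean",
) -> AssembledPredictors:
    """Source each model term for one issue month and harvest year.

    ``obs_lookup`` maps (region, variable, year, month) -> observed
    standardized anomaly (``panel.value_lookup("anomaly")``); ``dyn_anoms``
    is the frame from ``standardize_forecast_anomalies`` or the dict from
    ``dyn_anomaly_lookup`` (required for mode "DYN").
    """
    if mode not in SYSTEMS:
        raise ValueError(f"mode must be one of {SYSTEMS}, got {mode!r}")
    if issue_month not in ISSUE_MONTHS:
        raise ValueError(f"issue month must be in Jan-Jun, got {issue_month}")
    if mode == "DYN":
        if dyn_anoms is None:
            raise ValueError("mode='DYN' requires dyn_anoms")
        if isinstance(dyn_anoms, pd.DataFrame):
            dyn_anoms = dyn_anomaly_lookup(dyn_anoms)

    region = model.region
    issue_pos = season_position(issue_month)
    values: list = []
    sources: list[str] = []
    leads: list[int | None] = []

    persist_val: dict[str, float] = {}
    if mode == "PERSIST":
        known = month_before(issue_month)  # December for a January issue
        for var in {v for v, _, _ in model.terms}:
            ky = year - 1 if issue_month == 1 else year
            key = (region, var, ky, known)
            if key not in obs_lookup:
                raise CoverageError(f"persistence anomaly missing for {key}")
            persist_val[var] = float(obs_lookup[key])

    for var, month, _ in model.terms:
        pos = season_position(month)
        if mode == "BENCHMARK" or pos < issue_pos:
            values.append(_obs_anomaly(obs_lookup, region, var, year, month))
            sources.append("OBS")
            leads.append(None)
        elif mode == "PERSIST":
            values.append(persist_val[var])
            sources.append("PERSIST")
            leads.append(None)
        else:  # DYN future term
            lead = pos - issue_pos
            if lead > MAX_LEAD:
                raise CoverageError(
                    f"term {term_name(var, month)} needs lead {lead} > {MAX_LEAD} "
                    f"from issue month {issue_month}"
                )
            member_vals = dyn_anoms.get((region, var, issue_month, year, lead))
            if member_vals is None:
                raise CoverageError(
                    f"dynamical anomaly missing for ({region}, {var}, issue {issue_month}, "
                    f"year {year}, lead {lead})"
                )
            values.append(member_vals if ensemble == "members" else float(member_vals.mean()))
            sources.append("DYN")
            leads.append(lead)

    if ensemble == "members" and any(s == "DYN" for s in sources):
        n_mem = max(np.size(v) for v in values)
        mat = np.empty((len(values), n_mem))
        for i, v in enumerate(values):
            mat[i, :] = v
        arr = mat
    else:
        arr = np.array([float(np.mean(v)) for v in values])

    return AssembledPredictors(
        model=model, issue_month=issue_month, year=year, values=arr,
        sources=sources, leads=leads,
    )


def forecast_yields(model: RegressionModel, assembled: AssembledPredictors) -> np.ndarray:
    """Evaluate the linear model on assembled predictors.

    Returns a 1-element array for deterministic predictors, or one value
    per ensemble member when members are propagated.
    """
    vals = assembled.values
    if vals.ndim == 1:
        return np.atleast_1d(model.intercept + float(vals @ model.coefficients))
    return model.intercept + model.coefficients @ vals


def run_forecast_campaign(
    models: dict[tuple[str, str], RegressionModel],
    obs_panel: MonthlyClimatePanel,
    corrected: EnsembleForecastSet | None,
    years: list[int],
    issue_months: tuple[int, ...] = ISSUE_MONTHS,
    anomaly_method: str = "self",
    propagate_members: bool = True,
) -> pd.DataFrame:
    """Yield-anomaly forecast panels for DYN, PERSIST and BENCHMARK.

    Returns a long table (system, cereal, region, issue_month, year, member,
    value); ``member`` is NaN for deterministic values (the DYN ensemble
    mean, PERSIST and BENCHMARK) and 1..N for propagated DYN members.
    ``corrected=None`` skips the DYN system.
    """
    if not obs_panel.has_anomalies:
        raise ValueError("observations need an anomaly layer")
    obs_lookup = obs_panel.value_lookup("anomaly")
    dyn_lookup = None
    if corrected is not None:
        dyn_anoms = standardize_forecast_anomalies(
            corrected, method=anomaly_method, observations=obs_panel
        )
        dyn_lookup = dyn_anomaly_lookup(dyn_anoms)

    rows = []
    for (region, cereal), model in models.items():
        for im in issue_months:
            for year in years:
                asm_b = assemble_predictors(model, im, year, obs_lookup, "BENCHMARK")
                rows.append(("BENCHMARK", cereal, region, im, year, np.nan,
                             float(forecast_yields(model, asm_b)[0])))
                asm_p = assemble_predictors(model, im, year, obs_lookup, "PERSIST")
                rows.append(("PERSIST", cereal, region, im, year, np.nan,
                             float(forecast_yields(model, asm_p)[0])))
                if dyn_lookup is not None:
                    asm_m = assemble_predictors(
                        model, im, year, obs_lookup, "DYN", dyn_lookup, ensemble="mean"
                    )
                    rows.append(("DYN", cereal, region, im, year, np.nan,
                                 float(forecast_yields(model, asm_m)[0])))
                    if propagate_members:
                        asm_e = assemble_predictors(
                            model, im, year, obs_lookup, "DYN", dyn_lookup, ensemble="members"
                        )
                        member_vals = forecast_yields(model, asm_e)
                        for k, v in enumerate(member_vals, start=1):
                            rows.append(("DYN", cereal, region, im, year, float(k), float(v)))

    return pd.DataFrame(
        rows,
        columns=["system", "cereal", "region", "issue_month", "year", "member", "value"],
    )
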