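"""Sparse linear yield models: 27-term predictor pool, forward stepwise
selection, and leave-one-year-out cross-validation.

The candidate pool holds one standardized anomaly per (variable, growing
season month): 3 variables x Oct-Jun = 27 terms.  The season straddles the
calendar year, so harvest year y reads October-December from calendar year
y-1 and January-June from y.  Selection is pure forward: at each step, each
remaining candidate is tentatively added to an OLS fit and the one with the
smallest coefficient t-test p-value enters if it is below the entry
threshold (default 0.05); no removal step.  Because y and every column are
standardized, the fitted intercept is ~0.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from ._calendar import SEASON_MONTHS, climate_year
from .containers import (
    MonthlyClimatePanel,
    RegressionModel,
    VARIABLES,
    YieldAnomalySeries,
    parse_term,
    term_name,
)
from .errors import CoverageError, DegenerateInputError

#: season-ordered candidate terms: PR_Oct .. PR_Jun, TX_Oct .. TN_Jun
POOL_TERMS = [term_name(v, m) for v in VARIABLES for m in SEASON_MONTHS]


def build_predictor_pool(
    panel: MonthlyClimatePanel, region: str, harvest_years: list[int] | np.ndarray
) -> pd.DataFrame:
    """Predictor matrix: harvest years x 27 standardized anomaly columns.

    ``panel`` must carry the anomaly layer.  Any missing
    (variable, month, year) cell raises — a 26-row design cannot absorb
    silent gaps.
    """
    if not panel.has_anomalies:
        raise ValueError("panel has no anomaly layer; run standardize_monthly_anomalies first")
    lookup = panel.value_lookup("anomaly")
    harvest_years = [int(y) for y in harvest_years]
    data = {}
    for name in POOL_TERMS:
        var, month = parse_term(name)
        col = []
        for y in harvest_years:
            key = (region, var, climate_year(y, month), month)
            if key not in lookup or not np.isfinite(lookup[key]):
                raise CoverageError(f"anomaly missing for {key}")
            col.append(lookup[key])
        data[name] = col
    return pd.DataFrame(data, index=pd.Index(harvest_years, name="harvest_year"))


def _check_term_month(name: str) -> None:
    _, month = parse_term(name)
    if month not in SEASON_MONTHS:
        raise ValueError(f"predictor {name!r} is outside the Oct-Jun growing season")


def forward_stepwise(
    y: YieldAnomalySeries | pd.Series | np.ndarray,
    pool: pd.DataFrame,
    entry_alpha: float = 0.05,
    cereal: str = "",
    region: str = "",
) -> RegressionModel:
    """Forward stepwise OLS selection over the pool.

    Each step adds the candidate whose coefficient t-test p-value in the
    augmented fit is smallest, provided it is below ``entry_alpha``; ties
    are broken by larger absolute t statistic, then by pool column order.
    Candidates collinear with the selected set are skipped.  An empty
    selection returns a null model (no terms), not an error.
    """
    for name in pool.columns:
        _check_term_month(name)
    yv, cereal, region = _as_target(y, cereal, region)
    n = len(yv)
    if len(pool) != n:
        raise ValueError(f"pool has {len(pool)} rows but y has {n}")

    selected: list[str] = []
    trace: list[dict] = []
    remaining = list(pool.columns)
    while remaining:
        best = None  # (p, -|t|, order, name)
        for order, name in enumerate(remaining):
            X = sm.add_constant(pool[selected + [name]].to_numpy())
            if np.linalg.matrix_rank(X) < X.shape[1]:
                continue  # collinear with selected set
            fit = sm.OLS(yv, X).fit()
            p_val = float(fit.pvalues[-1])
            t_val = float(fit.tvalues[-1])
            if not np.isfinite(p_val):
                continue  # perfect fit already achieved; no defined entry test
            cand = (p_val, -abs(t_val), order, name)
            if best is None or cand < best:
                best = cand
        if best is None or best[0] >= entry_alpha:
            break
        p_val, neg_t, _, name = best
        selected.append(name)
        remaining.remove(name)
        trace.append({"term": name, "p_entry": p_val, "t_entry": -neg_t})

    if selected:
        X = sm.add_constant(pool[selected].to_numpy())
        fit = sm.OLS(yv, X).fit()
        intercept = float(fit.params[0])
        coefs = fit.params[1:]
        terms = [(*parse_term(nm), float(c)) for nm, c in zip(selected, coefs)]
    else:
        intercept = float(np.mean(yv))
        terms = []

    model = RegressionModel(
        cereal=cereal, region=region, terms=terms, intercept=intercept, trace=trace
    )
    if terms:
        model.metrics = fit_metrics(model, yv, pool)
    else:
        model.metrics = {"R": None, "R2_adj": None, "MAE": float(np.mean(np.abs(yv - intercept)))}
    return model


def _as_target(y, cereal: str, region: str) -> tuple[np.ndarray, str, str]:
    if isinstance(y, YieldAnomalySeries):
        return y.anomalies, cereal or y.cereal, region or y.region
    if isinstance(y, pd.Series):
        return y.to_numpy(dtype=float), cereal, region
    return np.asarray(y, dtype=float), cereal, region


def _predict(model: RegressionModel, pool: pd.DataFrame) -> np.ndarray:
    if not model.terms:
        return np.full(len(pool), model.intercept)
    return model.predict(pool[model.term_names].to_numpy())


def fit_metrics(
    model: RegressionModel, y: YieldAnomalySeries | pd.Series | np.ndarray, pool: pd.DataFrame
) -> dict:
    """Pearson R, adjusted R^2 and MAE of the model's in-sample predictions.

    R2_adj = 1 - (1 - R^2)(n - 1)/(n - p - 1) with p = number of selected
    terms.  Zero-variance predictions leave R undefined and raise.
    """
    yv, _, _ = _as_target(y, "", "")
    pred = _predict(model, pool)
    return _metric_dict(pred, yv, n_terms=len(model.terms))


def _metric_dict(pred: np.ndarray, obs: np.ndarray, n_terms: int, suffix: str = "") -> dict:
    if np.std(pred) < 1e-12:
        raise DegenerateInputError("predictions have zero variance; Pearson R undefined")
    r = float(stats.pearsonr(pred, obs)[0])
    n = len(obs)
    r2 = r**2
    denom = n - n_terms - 1
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / denom if denom > 0 else np.nan
    mae = float(np.mean(np.abs(pred - obs)))
    return {f"R{suffix}": r, f"R2_adj{suffix}": float(r2_adj), f"MAE{suffix}": mae}


def leave_one_year_out_cv(
    y: YieldAnomalySeries | pd.Series | np.ndarray,
    pool: pd.DataFrame,
    model: RegressionModel | None = None,
    mode: str = "A",
    entry_alpha: float = 0.05,
) -> tuple[np.ndarray, dict]:
    """Leave-one-year-out cross-validated predictions and metrics.

    Mode "A" (default) keeps the full-data selected term set fixed and
    refits only the coefficients on each fold; mode "B" reruns the entire
    stepwise selection inside each fold (a fold whose selection comes up
    empty predicts the anomaly mean, 0).  Returns the assembled
    out-of-sample prediction vector and {R_cv, R2_adj_cv, MAE_cv, cv_mode}.
    """
    yv, cereal, region = _as_target(y, "", "")
    n = len(yv)
    if mode not in ("A", "B"):
        raise ValueError(f"cv mode must be 'A' or 'B', got {mode!r}")
    if mode == "A":
        if model is None:
            model = forward_stepwise(y, pool, entry_alpha, cereal=cereal, region=region)
        names = model.term_names
    preds = np.empty(n)
    mask = np.ones(n, dtype=bool)
    for j in range(n):
        mask[:] = True
        mask[j] = False
        pool_j = pool.iloc[mask]
        y_j = yv[mask]
        if mode == "A":
            if names:
                X = sm.add_constant(pool_j[names].to_numpy())
                fit = sm.OLS(y_j, X).fit()
                x_row = np.concatenate([[1.0], pool.iloc[j][names].to_numpy()])
                preds[j] = float(x_row @ fit.params)
            else:
                preds[j] = float(np.mean(y_j))
        else:
            fold_model = forward_stepwise(y_j, pool_j, entry_alpha)
            if fold_model.terms:
                preds[j] = float(
                    fold_model.predict(pool.iloc[[j]][fold_model.term_names].to_numpy())[0]
                )
            else:
                preds[j] = 0.0
    n_terms = len(model.terms) if (mode == "A" and model is not None) else 0
    metrics = _metric_dict(preds, yv, n_terms=n_terms, suffix="_cv")
    metrics["cv_mode"] = mode
    return preds, metrics


def fit_yield_model(
    y: YieldAnomalySeries,
    pool: pd.DataFrame,
    entry_alpha: float = 0.05,
    cv_mode: str = "A",
) -> RegressionModel:
    """Stepwise fit plus CV metrics in one call (the pipeline entry point)."""
    model = forward_stepwise(y, pool, entry_alpha)
    if model.terms:
        _, cv = leave_one_year_out_cv(y, pool, model=model, mode=cv_mode, entry_alpha=entry_alpha)
        model.cv_metrics = cv
    return model
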