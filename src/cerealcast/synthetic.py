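"""Seeded synthetic climate, ensemble hindcasts and cereal yield records.

The generators emulate the statistical structure the downstream analysis
assumes for Iberian rainfed winter cereals:

* monthly regional climate = a seasonal climatology plus AR(1)-persistent
  standardized interannual anomalies (so a persistence forecast has genuine
  skill);
* ensemble hindcasts whose signal is damped and whose noise grows with lead
  time, with imposed additive (temperature) and multiplicative
  (precipitation) biases, so mean bias correction is exercised;
* annual per-province production/area records driven by a known sparse
  linear model of standardized monthly anomalies plus a technological trend
  and noise, so model-recovery can be tested against the planted truth.

All randomness flows from ``SyntheticConfig.seed`` through per-product
``numpy`` generators: identical configs give bitwise-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._calendar import SEASON_MONTHS, climate_year, season_position, verification_month, verification_year
from .containers import EnsembleForecastSet, MonthlyClimatePanel, VARIABLES
from .errors import CoverageError

# Iberian-flavoured monthly climatology (index 0 = January).
# PR: monthly accumulated precipitation [mm]; TX/TN: monthly means of daily
# max/min 2-m temperature [K].  Interannual SDs are broadly Mediterranean:
# wet-season precipitation varies by ~40-50% of its mean, temperatures by
# 1-1.5 K.
_DEFAULT_CLIMATOLOGY: dict[str, tuple[tuple[float, ...], tuple[float, ...]]] = {
    "PR": (
        (55.0, 50.0, 45.0, 55.0, 50.0, 30.0, 15.0, 18.0, 35.0, 60.0, 65.0, 60.0),
        (25.0, 24.0, 22.0, 24.0, 22.0, 15.0, 9.0, 10.0, 18.0, 27.0, 28.0, 26.0),
    ),
    "TX": (
        (283.0, 285.0, 288.0, 291.0, 295.0, 301.0, 305.0, 305.0, 300.0, 293.0, 287.0, 283.0),
        (1.5, 1.5, 1.5, 1.4, 1.4, 1.3, 1.2, 1.2, 1.3, 1.4, 1.4, 1.5),
    ),
    "TN": (
        (274.0, 275.0, 277.0, 279.0, 283.0, 288.0, 291.0, 291.0, 288.0, 283.0, 278.0, 275.0),
        (1.3, 1.3, 1.3, 1.2, 1.2, 1.1, 1.0, 1.0, 1.1, 1.2, 1.2, 1.3),
    ),
}

# Planted sparse models per (region, cereal): published-regime structures
# (March/May maximum temperature hurting, April precipitation helping, the
# southern region mixing in winter predictors).
_DEFAULT_TRUE_MODEL: dict[tuple[str, str], list[tuple[str, int, float]]] = {
    ("region1", "wheat"): [("TX", 3, -0.34), ("TX", 5, -0.36), ("PR", 4, 0.53)],
    ("region1", "barley"): [("TX", 3, -0.39), ("TX", 5, -0.33), ("PR", 4, 0.53)],
    ("region2", "wheat"): [("TX", 12, -0.25), ("PR", 11, 0.33), ("PR", 3, 0.49), ("PR", 4, 0.69)],
    ("region2", "barley"): [("TX", 11, -0.54), ("TX", 3, -0.36), ("TN", 10, 0.38),
                            ("PR", 4, 0.33), ("PR", 5, 0.48)],
}


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic study system.

    Defaults reproduce the analysis conditions: 1993-2019 monthly record,
    two 5-province regions, 25-member hindcasts with a 0-6 month lead
    horizon, and planted 3-5 term yield models whose noise level puts the
    population fit around R^2 ~ 0.7.
    """

    seed: int = 0
    start_year: int = 1993
    end_year: int = 2019
    #: region label -> number of provinces
    regions: Mapping[str, int] = field(default_factory=lambda: {"region1": 5, "region2": 5})
    #: variable -> (12 monthly means, 12 interannual SDs), January first
    month_climatology: Mapping[str, tuple[Sequence[float], Sequence[float]]] = field(
        default_factory=lambda: dict(_DEFAULT_CLIMATOLOGY)
    )
    #: month-to-month persistence of standardized anomalies
    ar1_coefficient: float = 0.35
    ensemble_size: int = 25
    #: per-lead (0..6) multiplier on the interannual SD giving forecast error SD
    lead_noise_scale: Sequence[float] = (0.6, 0.8, 0.95, 1.0, 1.0, 1.0, 1.0)
    #: per-lead (0..6) damping of the true anomaly in the forecast signal
    forecast_signal_damping: Sequence[float] = (0.9, 0.5, 0.3, 0.2, 0.15, 0.1, 0.1)
    #: additive K offset on TX/TN members; scalar or {(month, lead): offset}
    imposed_bias_temp: float | Mapping[tuple[int, int], float] = 1.5
    #: multiplicative factor on PR members; scalar or {(month, lead): factor}
    imposed_bias_precip: float | Mapping[tuple[int, int], float] = 1.3
    #: issue months for which hindcasts are generated
    issue_months: Sequence[int] = tuple(range(1, 13))
    #: (region, cereal) -> [(variable, calendar month, coefficient), ...]
    true_model: Mapping[tuple[str, str], list[tuple[str, int, float]]] = field(
        default_factory=lambda: {k: list(v) for k, v in _DEFAULT_TRUE_MODEL.items()}
    )
    #: SD of the noise added to the latent standardized yield anomaly
    yield_noise_sd: float = 0.45
    #: ton/ha per unit of standardized yield anomaly
    anomaly_scale: float = 0.4
    #: technological trend [ton/ha per year]
    tech_trend: float = 0.03
    #: mean yield level [ton/ha]
    base_yield: float = 2.9
    #: SD of per-province yield deviations from the regional value [ton/ha]
    province_noise_sd: float = 0.05
    #: cropped area of the first province [ha]; later provinces scale up 10% each
    province_area_ha: float = 100_000.0

    def __post_init__(self) -> None:
        if self.end_year < self.start_year:
            raise ValueError("end_year must be >= start_year")
        if not 0.0 <= self.ar1_coefficient < 1.0:
            raise ValueError("ar1_coefficient must be in [0, 1)")
        if self.ensemble_size < 1:
            raise ValueError("ensemble_size must be >= 1")
        means, _ = self.month_climatology["PR"]
        if any(m <= 0 for m in means):
            raise ValueError("precipitation climatology means must be positive")
        if len(self.lead_noise_scale) != 7 or len(self.forecast_signal_damping) != 7:
            raise ValueError("lead_noise_scale and forecast_signal_damping need 7 entries (leads 0-6)")
        for (region, cereal), terms in self.true_model.items():
            for var, month, _ in terms:
                if month not in SEASON_MONTHS:
                    raise ValueError(
                        f"true_model term month {month} for ({region}, {cereal}) "
                        "is outside the Oct-Jun growing season"
                    )
                if var not in VARIABLES:
                    raise ValueError(f"unknown variable {var!r} in true_model")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent generator for one product (0 climate, 1 hindcast, 2 yield)."""
        return np.random.default_rng([int(self.seed), stream])

    def bias_temp(self, month: int, lead: int) -> float:
        b = self.imposed_bias_temp
        # mapping cells not listed default to no bias
        return float(b.get((month, lead), 0.0)) if isinstance(b, Mapping) else float(b)

    def bias_precip(self, month: int, lead: int) -> float:
        b = self.imposed_bias_precip
        return float(b.get((month, lead), 1.0)) if isinstance(b, Mapping) else float(b)


def generate_monthly_climate(config: SyntheticConfig) -> MonthlyClimatePanel:
    """Monthly regional series: climatology + SD * AR(1) standardized anomaly.

    One AR(1) chain per (region, variable) runs across the continuous month
    sequence (December links to the following January), started from its
    stationary N(0, 1) distribution.  Precipitation is floored at zero after
    adding the anomaly.  The unfloored chain is kept in a ``z_true`` column
    as generator truth for the hindcast and yield generators.
    """
    rng = config.rng(0)
    years = np.arange(config.start_year, config.end_year + 1)
    n_months = 12 * len(years)
    phi = config.ar1_coefficient
    innov_sd = np.sqrt(1.0 - phi**2)

    month_idx = np.tile(np.arange(12), len(years))
    year_col = np.repeat(years, 12)

    frames = []
    for region in config.regions:
        for var in VARIABLES:
            means = np.asarray(config.month_climatology[var][0], dtype=float)
            sds = np.asarray(config.month_climatology[var][1], dtype=float)
            z = np.empty(n_months)
            z[0] = rng.standard_normal()
            eps = rng.standard_normal(n_months - 1)
            for t in range(1, n_months):
                z[t] = phi * z[t - 1] + innov_sd * eps[t - 1]
            value = means[month_idx] + sds[month_idx] * z
            if var == "PR":
                value = np.maximum(value, 0.0)
            frames.append(
                pd.DataFrame(
                    {
                        "region": region,
                        "variable": var,
                        "year": year_col,
                        "month": month_idx + 1,
                        "value": value,
                        "z_true": z,
                    }
                )
            )
    panel = MonthlyClimatePanel(pd.concat(frames, ignore_index=True))
    # physically TN should not exceed TX; with the default >=6 K climatological
    # gap this never binds in practice, but enforce it anyway
    _clip_tn_below_tx(panel.data)
    return panel


def _clip_tn_below_tx(data: pd.DataFrame) -> None:
    wide = data.pivot_table(index=["region", "year", "month"], columns="variable", values="value")
    if not {"TX", "TN"} <= set(wide.columns):
        return
    bad = wide[wide["TN"] > wide["TX"]]
    for (region, year, month), row in bad.iterrows():
        sel = (
            (data["region"] == region)
            & (data["year"] == year)
            & (data["month"] == month)
            & (data["variable"] == "TN")
        )
        data.loc[sel, "value"] = row["TX"]


def _true_anomaly_lookup(truth: MonthlyClimatePanel, config: SyntheticConfig) -> dict:
    """(region, variable, year, month) -> standardized truth anomaly."""
    if "z_true" in truth.data.columns:
        return truth.value_lookup("z_true")
    out = {}
    for (region, var, year, month), value in truth.value_lookup().items():
        means, sds = config.month_climatology[var]
        out[(region, var, year, month)] = (value - means[month - 1]) / sds[month - 1]
    return out


def generate_ensemble_hindcasts(
    truth: MonthlyClimatePanel, config: SyntheticConfig
) -> EnsembleForecastSet:
    """Raw (biased) ensemble hindcasts of the synthetic truth.

    Each member at (issue month m, lead lt, year) is built around the
    verification month m_v = m + lt:

        member = clim(m_v) + damping(lt) * sd(m_v) * z_true(m_v, y_v)
                          + noise(lt) * sd(m_v) * eps

    with eps i.i.d. standard normal per member.  Precipitation is floored at
    zero, then the imposed bias is applied (multiplicative for PR, additive
    for TX/TN).  Issue dates whose verification month falls outside the truth
    panel are omitted.
    """
    rng = config.rng(1)
    years = np.array(truth.years())
    year_set = set(int(y) for y in years)
    n_mem = config.ensemble_size
    damping = np.asarray(config.forecast_signal_damping, dtype=float)
    noise = np.asarray(config.lead_noise_scale, dtype=float)
    z_lookup = _true_anomaly_lookup(truth, config)

    rows_region, rows_var, rows_iy, rows_im, rows_lead, rows_member, rows_value = (
        [], [], [], [], [], [], []
    )
    members = np.arange(1, n_mem + 1)
    for region in config.regions:
        for var in VARIABLES:
            means = np.asarray(config.month_climatology[var][0], dtype=float)
            sds = np.asarray(config.month_climatology[var][1], dtype=float)
            for im in config.issue_months:
                for lt in range(7):
                    mv = verification_month(im, lt)
                    for iy in years:
                        yv = verification_year(int(iy), im, lt)
                        if yv not in year_set:
                            continue
                        z = z_lookup.get((region, var, yv, mv))
                        if z is None:
                            raise CoverageError(
                                f"truth panel missing ({region}, {var}, {yv}, {mv})"
                            )
                        eps = rng.standard_normal(n_mem)
                        vals = (
                            means[mv - 1]
                            + damping[lt] * sds[mv - 1] * z
                            + noise[lt] * sds[mv - 1] * eps
                        )
                        if var == "PR":
                            vals = np.maximum(vals, 0.0)
                            vals = vals * config.bias_precip(im, lt)
                        else:
                            vals = vals + config.bias_temp(im, lt)
                        rows_region.append(np.repeat(region, n_mem))
                        rows_var.append(np.repeat(var, n_mem))
                        rows_iy.append(np.repeat(int(iy), n_mem))
                        rows_im.append(np.repeat(im, n_mem))
                        rows_lead.append(np.repeat(lt, n_mem))
                        rows_member.append(members)
                        rows_value.append(vals)

    data = pd.DataFrame(
        {
            "region": np.concatenate(rows_region),
            "variable": np.concatenate(rows_var),
            "issue_year": np.concatenate(rows_iy),
            "issue_month": np.concatenate(rows_im),
            "lead": np.concatenate(rows_lead),
            "member": np.concatenate(rows_member),
            "value": np.concatenate(rows_value),
        }
    )
    return EnsembleForecastSet(data, corrected=False)


def generate_yield_records(
    climate: MonthlyClimatePanel, config: SyntheticConfig
) -> pd.DataFrame:
    """Per-province annual production [ton] and area [ha] records.

    The latent standardized regional anomaly for harvest year y is the
    planted linear combination of standardized monthly climate anomalies
    (October-December read from calendar year y-1, January-June from y)
    plus N(0, yield_noise_sd^2) noise.  Regional yield [ton/ha] is

        base_yield + tech_trend * (y - first_harvest) + anomaly_scale * a(y)

    and provinces deviate from it by small i.i.d. noise; production is
    yield * area with fixed per-province areas.
    """
    rng = config.rng(2)
    z_lookup = _true_anomaly_lookup(climate, config)
    harvest_years = np.arange(config.start_year + 1, config.end_year + 1)
    first_harvest = int(harvest_years[0])

    records = []
    for (region, cereal), terms in config.true_model.items():
        if region not in config.regions:
            raise ValueError(f"true_model region {region!r} not in config.regions")
        latent = np.zeros(len(harvest_years))
        for var, month, coef in terms:
            for i, y in enumerate(harvest_years):
                cy = climate_year(int(y), month)
                z = z_lookup.get((region, var, cy, month))
                if z is None:
                    raise CoverageError(f"climate panel missing ({region}, {var}, {cy}, {month})")
                latent[i] += coef * z
        latent = latent + config.yield_noise_sd * rng.standard_normal(len(harvest_years))
        regional_yield = (
            config.base_yield
            + config.tech_trend * (harvest_years - first_harvest)
            + config.anomaly_scale * latent
        )
        n_prov = config.regions[region]
        for p in range(n_prov):
            area = config.province_area_ha * (1.0 + 0.1 * p)
            prov_yield = regional_yield + config.province_noise_sd * rng.standard_normal(
                len(harvest_years)
            )
            prov_yield = np.maximum(prov_yield, 0.0)
            records.append(
                pd.DataFrame(
                    {
                        "province": f"{region}_p{p + 1}",
                        "region": region,
                        "cereal": cereal,
                        "year": harvest_years,
                        "production_ton": prov_yield * area,
                        "area_ha": area,
                    }
                )
            )
    return pd.concat(records, ignore_index=True)


def with_seed(config: SyntheticConfig, seed: int) -> SyntheticConfig:
    """Copy of ``config`` with a different seed (other conditions unchanged)."""
    return replace(config, seed=seed)
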