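"""In-memory containers for climate panels, forecast sets, yields and models.

All tabular payloads are long-format :class:`pandas.DataFrame` objects with
fixed column schemas, so every container round-trips losslessly through CSV.
The dataclasses add schema validation and the small amount of domain logic
(verification-month arithmetic, model serialization) the pipeline needs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._calendar import ABBR_MONTH, MONTH_ABBR, verification_month, verification_year
from .errors import CoverageError

VARIABLES = ("PR", "TX", "TN")

CLIMATE_COLUMNS = ["region", "variable", "year", "month", "value"]
FORECAST_COLUMNS = ["region", "variable", "issue_year", "issue_month", "lead", "member", "value"]
YIELD_COLUMNS = ["province", "region", "cereal", "year", "production_ton", "area_ha"]


@dataclass
class MonthlyClimatePanel:
    """Regional monthly climate series, optionally with standardized anomalies.

    ``data`` columns: region, variable (PR mm / TX K / TN K), year, month,
    value; optional ``anomaly`` (unitless standardized, per calendar month
    across years) and ``z_true`` (generator truth, synthetic data only).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in CLIMATE_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"climate panel missing columns {missing}")

    @property
    def has_anomalies(self) -> bool:
        return "anomaly" in self.data.columns

    def regions(self) -> list[str]:
        return sorted(self.data["region"].unique())

    def years(self) -> list[int]:
        return sorted(self.data["year"].unique())

    def select(self, region: str, variable: str) -> pd.DataFrame:
        sub = self.data[(self.data["region"] == region) & (self.data["variable"] == variable)]
        if sub.empty:
            raise CoverageError(f"no data for region={region!r} variable={variable!r}")
        return sub

    def value_lookup(self, column: str = "value") -> dict:
        """Dict keyed by (region, variable, year, month) for fast pointwise access."""
        d = self.data
        return dict(
            zip(
                zip(d["region"], d["variable"], d["year"].astype(int), d["month"].astype(int)),
                d[column],
            )
        )

    def validate(self) -> None:
        """Check physical invariants: PR >= 0 and TX >= TN where coincident."""
        pr = self.data[self.data["variable"] == "PR"]
        if (pr["value"] < 0).any():
            raise ValueError("negative precipitation in climate panel")
        wide = self.data.pivot_table(
            index=["region", "year", "month"], columns="variable", values="value"
        )
        if {"TX", "TN"} <= set(wide.columns):
            both = wide.dropna(subset=["TX", "TN"])
            if (both["TX"] < both["TN"]).any():
                raise ValueError("TX < TN for some (region, year, month)")

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "MonthlyClimatePanel":
        return cls(pd.read_csv(path))


@dataclass
class EnsembleForecastSet:
    """Ensemble forecasts indexed by (issue month, lead 0-6, member, issue year).

    ``data`` columns: region, variable, issue_year, issue_month, lead, member,
    value.  ``corrected`` flags whether the mean bias correction has been
    applied.  Lead 0 verifies the issue month itself.
    """

    data: pd.DataFrame
    corrected: bool = False

    def __post_init__(self) -> None:
        missing = [c for c in FORECAST_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"forecast set missing columns {missing}")

    def with_verification(self) -> pd.DataFrame:
        """Copy of the table with verification month/year columns added."""
        d = self.data.copy()
        im = d["issue_month"].to_numpy(int)
        lt = d["lead"].to_numpy(int)
        d["verif_month"] = (im + lt - 1) % 12 + 1
        d["verif_year"] = d["issue_year"].to_numpy(int) + (im + lt - 1) // 12
        return d

    def ensemble_mean(self) -> pd.DataFrame:
        keys = ["region", "variable", "issue_year", "issue_month", "lead"]
        return self.data.groupby(keys, as_index=False)["value"].mean()

    def grid(self) -> pd.DataFrame:
        """Unique (variable, issue_month, lead) cells present in the set."""
        return self.data[["variable", "issue_month", "lead"]].drop_duplicates()

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False, float_format="%.6f")

    @classmethod
    def from_csv(cls, path: str | Path, corrected: bool = False) -> "EnsembleForecastSet":
        return cls(pd.read_csv(path), corrected=corrected)


@dataclass
class YieldAnomalySeries:
    """Standardized, linearly detrended annual yield anomalies for one region/cereal.

    ``provenance`` records the raw ton/ha values and the trend slope,
    intercept and SD removed, so the transform is reproducible.
    """

    region: str
    cereal: str
    years: np.ndarray
    anomalies: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.anomalies = np.asarray(self.anomalies, dtype=float)
        if self.years.shape != self.anomalies.shape:
            raise ValueError("years and anomalies must have equal length")

    def as_series(self) -> pd.Series:
        return pd.Series(self.anomalies, index=self.years, name="anomaly")


@dataclass
class CorrectionFactors:
    """Mean-correction factors per (variable, issue month, lead).

    Multiplicative for precipitation (unitless ratio, > 0), additive for
    TX/TN (K).  ``obs_climatology`` keeps the observational multiannual means
    of the verification months the factors were computed against.
    """

    table: pd.DataFrame  # columns: region, variable, issue_month, lead, alpha
    obs_climatology: pd.DataFrame  # columns: region, variable, month, mean

    def lookup(self) -> dict:
        t = self.table
        return dict(
            zip(
                zip(t["region"], t["variable"], t["issue_month"].astype(int), t["lead"].astype(int)),
                t["alpha"],
            )
        )

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(
        cls, path: str | Path, obs_climatology: pd.DataFrame | None = None
    ) -> "CorrectionFactors":
        return cls(pd.read_csv(path), obs_climatology if obs_climatology is not None else pd.DataFrame())


def term_name(variable: str, month: int) -> str:
    """Canonical predictor label, e.g. ('PR', 4) -> 'PR_Apr'."""
    return f"{variable}_{MONTH_ABBR[month]}"


def parse_term(name: str) -> tuple[str, int]:
    var, abbr = name.split("_")
    return var, ABBR_MONTH[abbr]


@dataclass
class RegressionModel:
    """Sparse linear yield model on standardized monthly anomalies.

    ``terms`` is the ordered list of (variable, calendar month, coefficient)
    selected by forward stepwise regression; coefficients are unitless because
    both sides are standardized.  ``trace`` records the entry p-value of each
    term in selection order.
    """

    cereal: str
    region: str
    terms: list[tuple[str, int, float]]
    intercept: float = 0.0
    metrics: dict = field(default_factory=dict)       # R, R2_adj, MAE
    cv_metrics: dict = field(default_factory=dict)    # R_cv, R2_adj_cv, MAE_cv, mode
    trace: list[dict] = field(default_factory=list)

    @property
    def term_names(self) -> list[str]:
        return [term_name(v, m) for v, m, _ in self.terms]

    @property
    def coefficients(self) -> np.ndarray:
        return np.array([c for _, _, c in self.terms], dtype=float)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Evaluate the linear model; X has one column per term (in order)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != len(self.terms):
            raise ValueError(f"expected {len(self.terms)} predictor columns, got {X.shape[1]}")
        return self.intercept + X @ self.coefficients

    def last_predictor_month(self) -> int | None:
        """Latest term month in season order (None for the null model)."""
        from ._calendar import season_position

        if not self.terms:
            return None
        return max((m for _, m, _ in self.terms), key=season_position)

    def to_dict(self) -> dict:
        return {
            "cereal": self.cereal,
            "region": self.region,
            "terms": [
                {"variable": v, "month": MONTH_ABBR[m], "coefficient": c}
                for v, m, c in self.terms
            ],
            "intercept": self.intercept,
            "metrics": self.metrics,
            "cv_metrics": self.cv_metrics,
            "trace": self.trace,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_dict(cls, d: dict) -> "RegressionModel":
        terms = [
            (t["variable"], ABBR_MONTH[t["month"]], float(t["coefficient"]))
            for t in d["terms"]
        ]
        return cls(
            cereal=d["cereal"],
            region=d["region"],
            terms=terms,
            intercept=float(d.get("intercept", 0.0)),
            metrics=d.get("metrics", {}),
            cv_metrics=d.get("cv_metrics", {}),
            trace=d.get("trace", []),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "RegressionModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def load_reference_models() -> dict[tuple[str, str], RegressionModel]:
    """Built-in wheat/barley models for two Spanish regions.

    These are published regression structures for rainfed winter cereals in
    Iberia (standardized anomaly scale), shipped so forecasting can be
    exercised without refitting.  Keyed by (region, cereal).
    """
    root = Path(__file__).parent / "data" / "reference_models"
    out: dict[tuple[str, str], RegressionModel] = {}
    for p in sorted(root.glob("*.json")):
        m = RegressionModel.from_json(p)
        out[(m.region, m.cereal)] = m
    return out
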