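"""End-to-end orchestration: generate/load -> preprocess -> correct -> fit
-> forecast -> verify.

Stages communicate only through serialized files inside the run directory,
so each stage can be re-run and inspected independently:

    climate.csv               monthly regional climate (raw, + truth column
                              for synthetic runs)
    yields.csv                per-province production/area records
    hindcasts_raw.csv         raw biased ensemble hindcasts
    climate_anoms.csv         climate with the standardized anomaly layer
    yield_anoms.csv           standardized detrended yield anomalies
    correction_factors.csv    alpha(region, variable, issue month, lead)
    hindcasts_corrected.csv   mean-corrected hindcasts
    models/*.json             fitted regression models
    panels.csv                yield-anomaly forecasts per system
    report_scores.csv         FAR/H/HSS/RMSE/CRPS per issue month
    report_pdiff.csv          pooled and per-month RMSE percent differences
    summary.json              headline numbers

``manifest.json`` records the full (defaulted) configuration, its hash, the
seed and package versions; rerunning with the same configuration reproduces
byte-identical CSV outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from ._calendar import ISSUE_MONTHS
from .containers import CorrectionFactors, EnsembleForecastSet, MonthlyClimatePanel, RegressionModel
from .bias_correction import apply_correction, compute_correction_factors
from .forecasting import run_forecast_campaign
from .preprocessing import standardize_monthly_anomalies, yield_anomaly_series
from .synthetic import SyntheticConfig, generate_ensemble_hindcasts, generate_monthly_climate, generate_yield_records
from .verification import build_report
from .yield_model import build_predictor_pool, fit_yield_model

log = logging.getLogger("cerealcast")

STAGES = ("simulate", "preprocess", "correct", "fit", "forecast", "verify")


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run.

    ``input_mode="synthetic"`` generates all inputs from ``seed``;
    ``input_mode="files"`` reads climate/yields/hindcasts CSVs written in
    the same dialect (e.g. by a previous synthetic run, or user-supplied
    real data).
    """

    input_mode: str = "synthetic"
    seed: int = 0
    start_year: int = 1993
    end_year: int = 2019
    ensemble_size: int = 25
    ar1_coefficient: float = 0.35
    yield_noise_sd: float = 0.45
    bias_temp: float = 1.5
    bias_precip: float = 1.3
    issue_months: tuple[int, ...] = ISSUE_MONTHS
    entry_alpha: float = 0.05
    cv_mode: str = "A"
    anomaly_method: str = "self"          # forecast-anomaly standardization
    pdiff_convention: str = "text"        # headline sign: "text" or "eq7"
    propagate_members: bool = True
    climate_csv: str | None = None        # file mode inputs
    yields_csv: str | None = None
    hindcasts_csv: str | None = None

    def __post_init__(self) -> None:
        if self.input_mode not in ("synthetic", "files"):
            raise ValueError(f"input_mode must be 'synthetic' or 'files', got {self.input_mode!r}")
        if self.input_mode == "files":
            for name in ("climate_csv", "yields_csv", "hindcasts_csv"):
                path = getattr(self, name)
                if path is None or not Path(path).exists():
                    raise FileNotFoundError(f"file mode requires existing {name}, got {path!r}")
        if self.cv_mode not in ("A", "B"):
            raise ValueError("cv_mode must be 'A' or 'B'")
        if self.pdiff_convention not in ("text", "eq7"):
            raise ValueError("pdiff_convention must be 'text' or 'eq7'")
        self.issue_months = tuple(int(m) for m in self.issue_months)

    def synthetic_config(self) -> SyntheticConfig:
        return SyntheticConfig(
            seed=self.seed,
            start_year=self.start_year,
            end_year=self.end_year,
            ensemble_size=self.ensemble_size,
            ar1_coefficient=self.ar1_coefficient,
            yield_noise_sd=self.yield_noise_sd,
            imposed_bias_temp=self.bias_temp,
            imposed_bias_precip=self.bias_precip,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["issue_months"] = list(self.issue_months)
        return d

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


def _harvest_years(config: RunConfig) -> list[int]:
    return list(range(config.start_year + 1, config.end_year + 1))


def stage_simulate(config: RunConfig, outdir: Path) -> None:
    """Generate (or, in file mode, import) climate, hindcasts and yields."""
    if config.input_mode == "files":
        for src, dst in (
            (config.climate_csv, "climate.csv"),
            (config.yields_csv, "yields.csv"),
            (config.hindcasts_csv, "hindcasts_raw.csv"),
        ):
            (outdir / dst).write_text(Path(src).read_text())
        return
    syn = config.synthetic_config()
    climate = generate_monthly_climate(syn)
    climate.to_csv(outdir / "climate.csv")
    hindcasts = generate_ensemble_hindcasts(climate, syn)
    hindcasts.to_csv(outdir / "hindcasts_raw.csv")
    records = generate_yield_records(climate, syn)
    records.to_csv(outdir / "yields.csv", index=False)


def stage_preprocess(config: RunConfig, outdir: Path) -> None:
    """Standardize climate anomalies and detrended yield anomalies."""
    climate = MonthlyClimatePanel.from_csv(outdir / "climate.csv")
    with_anoms = standardize_monthly_anomalies(climate)
    with_anoms.to_csv(outdir / "climate_anoms.csv")

    records = pd.read_csv(outdir / "yields.csv")
    rows = []
    provenance = {}
    for (region, cereal), _ in records.groupby(["region", "cereal"]):
        series = yield_anomaly_series(records, region, cereal)
        provenance[f"{region}/{cereal}"] = {
            k: v for k, v in series.provenance.items() if k != "raw_values"
        }
        for year, value in zip(series.years, series.anomalies):
            rows.append({"region": region, "cereal": cereal, "year": int(year), "anomaly": value})
    pd.DataFrame(rows).to_csv(outdir / "yield_anoms.csv", index=False)
    (outdir / "yield_provenance.json").write_text(json.dumps(provenance, indent=2) + "\n")


def stage_correct(config: RunConfig, outdir: Path) -> None:
    """Mean bias correction of the raw hindcasts against the observations."""
    climate = MonthlyClimatePanel.from_csv(outdir / "climate.csv")
    raw = EnsembleForecastSet.from_csv(outdir / "hindcasts_raw.csv")
    factors = compute_correction_factors(raw, climate)
    factors.to_csv(outdir / "correction_factors.csv")
    corrected = apply_correction(raw, factors)
    corrected.to_csv(outdir / "hindcasts_corrected.csv")


def stage_fit(config: RunConfig, outdir: Path) -> None:
    """Forward stepwise regression per (region, cereal), with CV metrics."""
    panel = MonthlyClimatePanel.from_csv(outdir / "climate_anoms.csv")
    yields = pd.read_csv(outdir / "yield_anoms.csv")
    years = _harvest_years(config)
    model_dir = outdir / "models"
    model_dir.mkdir(exist_ok=True)
    for (region, cereal), block in yields.groupby(["region", "cereal"]):
        block = block.sort_values("year")
        if list(block["year"]) != years:
            raise ValueError(f"yield anomalies for {region}/{cereal} do not cover {years[0]}-{years[-1]}")
        pool = build_predictor_pool(panel, region, years)
        model = fit_yield_model(
            block.set_index("year")["anomaly"], pool,
            entry_alpha=config.entry_alpha, cv_mode=config.cv_mode,
        )
        model.cereal, model.region = cereal, region
        model.to_json(model_dir / f"{region}_{cereal}.json")
        log.info("fitted %s/%s: %d terms, R=%s", region, cereal, len(model.terms),
                 model.metrics.get("R"))


def stage_forecast(config: RunConfig, outdir: Path) -> None:
    """Forecast campaign for the DYN, PERSIST and BENCHMARK systems."""
    panel = MonthlyClimatePanel.from_csv(outdir / "climate_anoms.csv")
    corrected = EnsembleForecastSet.from_csv(outdir / "hindcasts_corrected.csv", corrected=True)
    models = {}
    for path in sorted((outdir / "models").glob("*.json")):
        m = RegressionModel.from_json(path)
        models[(m.region, m.cereal)] = m
    panels = run_forecast_campaign(
        models, panel, corrected, _harvest_years(config),
        issue_months=config.issue_months, anomaly_method=config.anomaly_method,
        propagate_members=config.propagate_members,
    )
    panels.to_csv(outdir / "panels.csv", index=False, float_format="%.8f")


def stage_verify(config: RunConfig, outdir: Path) -> None:
    """Contingency, RMSE/Pdiff and CRPS verification of the panels."""
    panels = pd.read_csv(outdir / "panels.csv")
    yields = pd.read_csv(outdir / "yield_anoms.csv")
    observations = {
        (region, cereal): block.set_index("year")["anomaly"]
        for (region, cereal), block in yields.groupby(["region", "cereal"])
    }
    report = build_report(panels, observations)
    report["scores"].to_csv(outdir / "report_scores.csv", index=False, float_format="%.8f")
    report["pdiff"].to_csv(outdir / "report_pdiff.csv", index=False, float_format="%.8f")

    pooled = report["pdiff"][report["pdiff"]["issue_month"] == "all"]
    col = "pdiff" if config.pdiff_convention == "text" else "pdiff_alt"
    summary = {
        "pdiff_convention": config.pdiff_convention,
        "pdiff": {
            f"{r['region']}/{r['cereal']}": float(r[col]) for _, r in pooled.iterrows()
        },
        "mean_hss_by_system": {
            system: float(block["HSS"].mean())
            for system, block in report["scores"].groupby("system")
        },
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "preprocess": stage_preprocess,
    "correct": stage_correct,
    "fit": stage_fit,
    "forecast": stage_forecast,
    "verify": stage_verify,
}


def run_pipeline(config: RunConfig, outdir: str | Path, stages: tuple[str, ...] = STAGES) -> Path:
    """Run the requested stages in order, persisting everything under ``outdir``.

    A failing stage leaves a FAILED marker naming the stage; partial
    outputs are retained for inspection.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": config.to_dict(),
        "config_hash": config.hash(),
        "seed": config.seed,
        "versions": _versions(),
        "stages": [],
    }
    for stage in stages:
        if stage not in _STAGE_FUNCS:
            raise ValueError(f"unknown stage {stage!r}")
        t0 = time.perf_counter()
        try:
            _STAGE_FUNCS[stage](config, outdir)
        except Exception as exc:
            (outdir / "FAILED").write_text(f"stage {stage} failed: {exc}\n")
            manifest["stages"].append({"stage": stage, "status": "failed", "error": str(exc)})
            (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
            raise RuntimeError(f"pipeline stage {stage!r} failed") from exc
        dt = time.perf_counter() - t0
        log.info("stage %s done in %.1fs", stage, dt)
        manifest["stages"].append({"stage": stage, "status": "ok", "seconds": round(dt, 2)})
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    failed = outdir / "FAILED"
    if failed.exists():
        failed.unlink()
    return outdir


def _versions() -> dict:
    import numpy, pandas, scipy, statsmodels

    from . import __version__

    return {
        "cerealcast": __version__,
        "numpy": numpy.__version__,
        "pandas": pandas.__version__,
        "scipy": scipy.__version__,
        "statsmodels": statsmodels.__version__,
    }
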