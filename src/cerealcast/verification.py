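"""Forecast verification: 2x2 contingency scores, RMSE comparison and CRPS.

The binary event is a loss year: standardized yield anomaly strictly below
zero.  From the 2x2 table (hits a, false alarms b, misses c, correct
negatives d):

    FAR = b / (a + b)          false alarm ratio
    H   = a / (a + c)          hit rate
    HSS = 2(ad - bc) / [(a + c)(c + d) + (a + b)(b + d)]

HSS is the fractional improvement over a chance forecast: 1 is perfect, 0
is no skill, negative means chance does better.  Undefined scores (zero
denominators) come back as NaN with an explicit reason, never as silent 0.

System accuracy is compared through the percent RMSE difference.  The
headline convention is negative-when-dynamical-wins:

    Pdiff = (RMSE_dyn / RMSE_per - 1) * 100

the opposite algebraic form (1 - RMSE_dyn / RMSE_per) * 100 is emitted
alongside as ``pdiff_alt``.

CRPS uses the standard ensemble estimator
mean_i |x_i - y| - 1/2 mean_ij |x_i - x_j|; a single-member ensemble
reduces it to the absolute error, so a deterministic system's CRPS is its
MAE.  A "fair" (unbiased, n/(n-1)-weighted spread) variant is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateInputError

PERCENTILES = (5, 25, 50, 75, 95)


@dataclass
class ContingencyTable:
    """2x2 event table; the event is anomaly < threshold in forecast/observation."""

    a: int  # hits: forecast yes, observed yes
    b: int  # false alarms: forecast yes, observed no
    c: int  # misses: forecast no, observed yes
    d: int  # correct negatives

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


def contingency(
    forecasts: np.ndarray, observations: np.ndarray, threshold: float = 0.0
) -> ContingencyTable:
    """Tally the 2x2 table; "yes" is value strictly below ``threshold``."""
    f = np.asarray(forecasts, dtype=float)
    o = np.asarray(observations, dtype=float)
    if f.size == 0:
        raise ValueError("empty input to contingency")
    if f.shape != o.shape:
        raise ValueError(f"length mismatch: {f.shape} vs {o.shape}")
    fy = f < threshold
    oy = o < threshold
    return ContingencyTable(
        a=int(np.sum(fy & oy)),
        b=int(np.sum(fy & ~oy)),
        c=int(np.sum(~fy & oy)),
        d=int(np.sum(~fy & ~oy)),
    )


def far(t: ContingencyTable) -> float:
    """False alarm ratio b/(a+b); NaN if no "yes" forecasts were made."""
    if t.a + t.b == 0:
        return float("nan")
    return t.b / (t.a + t.b)


def hit_rate(t: ContingencyTable) -> float:
    """Hit rate a/(a+c); NaN if the event never occurred."""
    if t.a + t.c == 0:
        return float("nan")
    return t.a / (t.a + t.c)


def pofd(t: ContingencyTable) -> float:
    """Probability of false detection b/(b+d); NaN if no non-events occurred."""
    if t.b + t.d == 0:
        return float("nan")
    return t.b / (t.b + t.d)


def hss(t: ContingencyTable) -> float:
    """Heidke skill score 2(ad-bc)/[(a+c)(c+d)+(a+b)(b+d)]; NaN on zero denominator."""
    denom = (t.a + t.c) * (t.c + t.d) + (t.a + t.b) * (t.b + t.d)
    if denom == 0:
        return float("nan")
    return 2.0 * (t.a * t.d - t.b * t.c) / denom


def score_table(t: ContingencyTable) -> dict:
    """All contingency scores, with a reason string for each undefined one."""
    out = {
        "a": t.a, "b": t.b, "c": t.c, "d": t.d,
        "FAR": far(t), "H": hit_rate(t), "HSS": hss(t), "POFD": pofd(t),
    }
    reasons = []
    if t.a + t.b == 0:
        reasons.append("FAR undefined: no event forecasts issued (a+b=0)")
    if t.a + t.c == 0:
        reasons.append("H undefined: event never observed (a+c=0)")
    if (t.a + t.c) * (t.c + t.d) + (t.a + t.b) * (t.b + t.d) == 0:
        reasons.append("HSS undefined: zero denominator")
    out["undefined"] = reasons
    return out


def rmse(forecasts: np.ndarray, observations: np.ndarray) -> float:
    f = np.asarray(forecasts, dtype=float)
    o = np.asarray(observations, dtype=float)
    if f.size == 0:
        raise ValueError("empty input to rmse")
    return float(np.sqrt(np.mean((f - o) ** 2)))


def pdiff(rmse_dyn: float, rmse_per: float) -> float:
    """Percent RMSE difference; negative when the dynamical system is more accurate."""
    if rmse_per <= 0:
        raise ValueError("persistence RMSE must be positive")
    return (rmse_dyn / rmse_per - 1.0) * 100.0


def pdiff_alt(rmse_dyn: float, rmse_per: float) -> float:
    """Opposite-sign algebraic form, (1 - RMSE_dyn/RMSE_per) * 100."""
    return -pdiff(rmse_dyn, rmse_per)


def crps_ensemble(
    members: np.ndarray, observation: float, fair: bool = False
) -> float:
    """CRPS of one ensemble forecast against a scalar observation."""
    x = np.asarray(members, dtype=float).ravel()
    m = x.size
    if m == 0:
        raise ValueError("empty ensemble")
    term1 = float(np.mean(np.abs(x - observation)))
    spread = float(np.mean(np.abs(x[:, None] - x[None, :])))
    if fair:
        if m < 2:
            raise ValueError("fair CRPS needs >= 2 members")
        spread *= m / (m - 1)
    return term1 - 0.5 * spread


def crps(
    ensembles: np.ndarray | list[np.ndarray],
    observations: np.ndarray,
    fair: bool = False,
) -> float:
    """Mean CRPS over years; ``ensembles`` is (n_years, n_members) or a list."""
    obs = np.asarray(observations, dtype=float)
    scores = [crps_ensemble(e, y, fair=fair) for e, y in zip(ensembles, obs, strict=True)]
    if not scores:
        raise ValueError("empty input to crps")
    return float(np.mean(scores))


def build_report(
    panels: pd.DataFrame,
    observations: dict[tuple[str, str], pd.Series],
    threshold: float = 0.0,
) -> dict:
    """Score forecast panels against observed yield anomalies.

    ``panels``: long table (system, cereal, region, issue_month, year,
    member, value) as produced by the forecast campaign; ``observations``
    maps (region, cereal) -> year-indexed anomaly Series.

    Returns:
      * "scores": one row per (cereal, region, system, issue_month) with
        contingency counts, FAR/H/HSS, RMSE, CRPS and the 5/25/50/75/95
        percentiles of forecast - observed differences;
      * "pdiff": one row per (cereal, region), DYN vs PERSIST RMSE pooled
        over all issue months (both sign conventions), plus per-month rows.

    Deterministic values (member NaN) drive the contingency and RMSE
    metrics; DYN members, where present, drive its CRPS.  PERSIST and
    BENCHMARK are deterministic, so their CRPS equals their MAE.
    """
    det = panels[panels["member"].isna()]
    mem = panels[panels["member"].notna()]

    score_rows = []
    for (cereal, region, system, im), block in det.groupby(
        ["cereal", "region", "system", "issue_month"]
    ):
        key = (region, cereal)
        if key not in observations:
            raise KeyError(f"no observed anomalies for {key}")
        obs = observations[key]
        merged = block.set_index("year")["value"].reindex(obs.index)
        if merged.isna().any():
            missing = list(merged[merged.isna()].index)
            raise ValueError(f"panel {cereal}/{region}/{system}/m{im} missing years {missing}")
        f = merged.to_numpy()
        o = obs.to_numpy()
        t = contingency(f, o, threshold)
        diffs = f - o

        mem_block = mem[
            (mem["cereal"] == cereal) & (mem["region"] == region)
            & (mem["system"] == system) & (mem["issue_month"] == im)
        ]
        if not mem_block.empty:
            ens = [
                mem_block[mem_block["year"] == y].sort_values("member")["value"].to_numpy()
                for y in obs.index
            ]
            crps_val = crps(ens, o)
        else:
            crps_val = float(np.mean(np.abs(diffs)))  # deterministic: CRPS == MAE

        row = {
            "cereal": cereal, "region": region, "system": system, "issue_month": int(im),
            "n": t.n, "RMSE": rmse(f, o), "MAE": float(np.mean(np.abs(diffs))),
            "CRPS": crps_val,
        }
        row.update({k: v for k, v in score_table(t).items() if k != "undefined"})
        row["undefined"] = "; ".join(score_table(t)["undefined"])
        for p, v in zip(PERCENTILES, np.percentile(diffs, PERCENTILES)):
            row[f"diff_p{p}"] = float(v)
        score_rows.append(row)
    scores = pd.DataFrame(score_rows)

    pdiff_rows = []
    systems = set(det["system"].unique())
    if {"DYN", "PERSIST"} <= systems:
        for (cereal, region), block in det.groupby(["cereal", "region"]):
            obs = observations[(region, cereal)]

            def _pooled_rmse(system: str, issue_month: int | None = None) -> float:
                sel = block[block["system"] == system]
                if issue_month is not None:
                    sel = sel[sel["issue_month"] == issue_month]
                merged = sel.merge(
                    obs.rename("obs"), left_on="year", right_index=True, how="inner"
                )
                return rmse(merged["value"].to_numpy(), merged["obs"].to_numpy())

            r_dyn, r_per = _pooled_rmse("DYN"), _pooled_rmse("PERSIST")
            pdiff_rows.append({
                "cereal": cereal, "region": region, "issue_month": "all",
                "rmse_dyn": r_dyn, "rmse_per": r_per,
                "pdiff": pdiff(r_dyn, r_per), "pdiff_alt": pdiff_alt(r_dyn, r_per),
            })
            for im in sorted(block["issue_month"].unique()):
                r_d, r_p = _pooled_rmse("DYN", im), _pooled_rmse("PERSIST", im)
                pdiff_rows.append({
                    "cereal": cereal, "region": region, "issue_month": int(im),
                    "rmse_dyn": r_d, "rmse_per": r_p,
                    "pdiff": pdiff(r_d, r_p), "pdiff_alt": pdiff_alt(r_d, r_p),
                })
    return {"scores": scores, "pdiff": pd.DataFrame(pdiff_rows)}
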