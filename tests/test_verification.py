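"""Contingency scores, RMSE percent difference and the ensemble CRPS."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cerealcast.verification import (
    ContingencyTable,
    build_report,
    contingency,
    crps,
    crps_ensemble,
    far,
    hit_rate,
    hss,
    pdiff,
    pdiff_alt,
    pofd,
    rmse,
    score_table,
)


class TestContingency:
    def test_identical_series_have_no_misclassifications(self):
        x = np.array([-1.2, 0.4, -0.3, 0.8])
        t = contingency(x, x)
        assert (t.b, t.c) == (0, 0)
        assert (t.a, t.d) == (2, 2)

    def test_sign_flipped_series_have_only_misclassifications(self):
        x = np.array([-1.2, 0.4, -0.3, 0.8])
        t = contingency(-x, x)
        assert (t.a, t.d) == (0, 0)
        assert (t.b, t.c) == (2, 2)

    def test_zero_anomaly_is_not_an_event(self):
        t = contingency(np.array([0.0]), np.array([0.0]))
        assert (t.a, t.b, t.c, t.d) == (0, 0, 0, 1)

    def test_against_brute_force_recount(self):
        rng = np.random.default_rng(3)
        f, o = rng.standard_normal(26), rng.standard_normal(26)
        t = contingency(f, o)
        a = b = c = d = 0
        for fi, oi in zip(f, o):
            if fi < 0 and oi < 0:
                a += 1
            elif fi < 0:
                b += 1
            elif oi < 0:
                c += 1
            else:
                d += 1
        assert (t.a, t.b, t.c, t.d) == (a, b, c, d)
        assert t.n == 26

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            contingency(np.array([]), np.array([]))


class TestCategoricalScores:
    def test_perfect_table(self):
        t = ContingencyTable(a=13, b=0, c=0, d=13)
        assert far(t) == 0.0
        assert hit_rate(t) == 1.0
        assert hss(t) == 1.0

    def test_independence_table_has_no_skill(self):
        # (9, 3, 3, 1): ad = bc = 9, the chance-forecast limit
        assert hss(ContingencyTable(9, 3, 3, 1)) == 0.0

    def test_direct_formula_arithmetic(self):
        t = ContingencyTable(10, 2, 3, 11)
        assert hss(t) == pytest.approx(208 / 338)
        assert far(t) == pytest.approx(2 / 12)
        assert hit_rate(t) == pytest.approx(10 / 13)
        assert pofd(t) == pytest.approx(2 / 13)

    def test_undefined_scores_are_nan_with_reason(self):
        t = ContingencyTable(0, 0, 5, 5)
        assert math.isnan(far(t))
        report = score_table(t)
        assert any("FAR" in r for r in report["undefined"])
        t2 = ContingencyTable(0, 5, 0, 5)
        assert math.isnan(hit_rate(t2))

    @settings(deadline=None, max_examples=100)
    @given(st.tuples(*[st.integers(0, 30)] * 4), st.integers(1, 5))
    def test_symmetry_and_scaling_invariances(self, counts, k):
        a, b, c, d = counts
        t = ContingencyTable(a, b, c, d)
        swapped = ContingencyTable(d, c, b, a)  # a<->d, b<->c
        h1, h2 = hss(t), hss(swapped)
        assert (math.isnan(h1) and math.isnan(h2)) or h1 == pytest.approx(h2)
        scaled = ContingencyTable(k * a, k * b, k * c, k * d)
        for score in (far, hit_rate):
            s1, s2 = score(t), score(scaled)
            assert (math.isnan(s1) and math.isnan(s2)) or s1 == pytest.approx(s2)


class TestPdiff:
    def test_equal_rmse_gives_zero(self):
        assert pdiff(0.5, 0.5) == 0.0

    def test_sixteen_percent_improvement(self):
        # dynamical RMSE at 84% of persistence: headline convention -16
        assert pdiff(0.84, 1.0) == pytest.approx(-16.0)

    @settings(deadline=None, max_examples=50)
    @given(st.floats(0.01, 10), st.floats(0.01, 10))
    def test_conventions_are_exact_negations(self, r_dyn, r_per):
        assert pdiff_alt(r_dyn, r_per) == pytest.approx(-pdiff(r_dyn, r_per))

    def test_zero_persistence_rmse_rejected(self):
        with pytest.raises(ValueError):
            pdiff(0.5, 0.0)


def _crps_integral(members: np.ndarray, y: float) -> float:
    """Exact CDF-integral CRPS: integral of (F(x) - 1{x >= y})^2 dx.

    F is the empirical step CDF; the integrand is piecewise constant
    between breakpoints, so the integral is a finite sum.
    """
    pts = np.sort(np.unique(np.concatenate([members, [y]])))
    m = len(members)
    total = 0.0
    for left, right in zip(pts[:-1], pts[1:]):
        x = 0.5 * (left + right)
        f = np.sum(np.sort(members) <= x) / m
        h = 1.0 if x >= y else 0.0
        total += (f - h) ** 2 * (right - left)
    return total


class TestCrps:
    def test_single_member_reduces_to_absolute_error(self):
        assert crps_ensemble(np.array([0.7]), 0.2) == pytest.approx(0.5)
        # deterministic system over years: CRPS equals MAE
        f = np.array([0.1, -0.5, 0.9])
        o = np.array([0.0, 0.2, 0.4])
        assert crps(f.reshape(-1, 1), o) == pytest.approx(np.mean(np.abs(f - o)))

    def test_perfect_ensemble_scores_zero(self):
        assert crps_ensemble(np.full(5, 1.3), 1.3) == pytest.approx(0.0)

    def test_hand_example_three_members(self):
        # members {0, 1, 2} vs observation 1: 2/3 - (1/2)(8/9) = 2/9
        assert crps_ensemble(np.array([0.0, 1.0, 2.0]), 1.0) == pytest.approx(2 / 9)

    @settings(deadline=None, max_examples=50)
    @given(
        st.lists(st.floats(-3, 3), min_size=1, max_size=8),
        st.floats(-3, 3),
    )
    def test_estimator_matches_cdf_integral(self, members, y):
        members = np.asarray(members)
        est = crps_ensemble(members, y)
        assert est == pytest.approx(_crps_integral(members, y), abs=1e-6)

    def test_fair_variant_removes_spread_bias(self):
        # fair CRPS rescales the spread term by m/(m-1)
        members = np.array([0.0, 1.0])
        assert crps_ensemble(members, 0.5, fair=True) == pytest.approx(0.5 - 0.5)
        with pytest.raises(ValueError):
            crps_ensemble(np.array([1.0]), 0.5, fair=True)

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValueError):
            crps_ensemble(np.array([]), 0.0)


def _mini_panels(values: dict, members: dict | None = None) -> pd.DataFrame:
    rows = []
    for (system, im, year), v in values.items():
        rows.append({"system": system, "cereal": "wheat", "region": "r1",
                     "issue_month": im, "year": year, "member": np.nan, "value": v})
    for (system, im, year, mem), v in (members or {}).items():
        rows.append({"system": system, "cereal": "wheat", "region": "r1",
                     "issue_month": im, "year": year, "member": float(mem), "value": v})
    return pd.DataFrame(rows)


class TestReport:
    def test_perfect_panel_scores_perfectly(self):
        obs = pd.Series([-0.5, 0.3, -0.1, 0.9], index=[2001, 2002, 2003, 2004])
        values = {("DYN", im, y): obs[y] for im in (1, 2) for y in obs.index}
        values |= {("PERSIST", im, y): obs[y] + 0.2 for im in (1, 2) for y in obs.index}
        report = build_report(_mini_panels(values), {("r1", "wheat"): obs})
        dyn = report["scores"][report["scores"]["system"] == "DYN"]
        assert np.allclose(dyn["FAR"], 0.0)
        assert np.allclose(dyn["H"], 1.0)
        assert np.allclose(dyn["HSS"], 1.0)
        assert np.allclose(dyn["RMSE"], 0.0)

    def test_deterministic_crps_equals_mae(self):
        obs = pd.Series([-0.5, 0.3, -0.1], index=[2001, 2002, 2003])
        values = {("PERSIST", 1, y): obs[y] + 0.3 * (-1) ** y for y in obs.index}
        report = build_report(_mini_panels(values), {("r1", "wheat"): obs})
        row = report["scores"].iloc[0]
        assert row["CRPS"] == pytest.approx(row["MAE"])

    def test_member_crps_used_for_dyn(self):
        obs = pd.Series([0.0, 1.0], index=[2001, 2002])
        values = {("DYN", 1, 2001): 1.0, ("DYN", 1, 2002): 1.0}
        members = {("DYN", 1, 2001, m): v for m, v in enumerate([0.0, 1.0, 2.0], 1)}
        members |= {("DYN", 1, 2002, m): 1.0 for m in (1, 2, 3)}
        report = build_report(_mini_panels(values, members), {("r1", "wheat"): obs})
        # year 2001: members {0,1,2} vs obs 0 -> 1 - 4/9 = 5/9; year 2002: 0
        assert report["scores"].iloc[0]["CRPS"] == pytest.approx(0.5 * (5 / 9 + 0.0))

    def test_pdiff_pooled_over_issue_months(self):
        obs = pd.Series([0.0, 0.0], index=[2001, 2002])
        values = {("DYN", im, y): 0.42 for im in (1, 2) for y in obs.index}
        values |= {("PERSIST", im, y): 0.5 for im in (1, 2) for y in obs.index}
        report = build_report(_mini_panels(values), {("r1", "wheat"): obs})
        pooled = report["pdiff"][report["pdiff"]["issue_month"] == "all"].iloc[0]
        assert pooled["pdiff"] == pytest.approx(-16.0)
        assert pooled["pdiff_alt"] == pytest.approx(16.0)

    def test_report_round_trips_through_csv(self, tmp_path):
        rng = np.random.default_rng(8)
        obs = pd.Series(rng.standard_normal(6), index=range(2001, 2007))
        values = {(s, im, y): rng.standard_normal()
                  for s in ("DYN", "PERSIST") for im in (1, 2, 3) for y in obs.index}
        panels = _mini_panels(values)
        path = tmp_path / "panels.csv"
        panels.to_csv(path, index=False)
        direct = build_report(panels, {("r1", "wheat"): obs})
        reread = build_report(pd.read_csv(path), {("r1", "wheat"): obs})
        pd.testing.assert_frame_equal(direct["scores"], reread["scores"])
        pd.testing.assert_frame_equal(direct["pdiff"], reread["pdiff"])

    def test_missing_year_in_panel_is_an_error(self):
        obs = pd.Series([0.1, 0.2], index=[2001, 2002])
        values = {("DYN", 1, 2001): 0.0}
        with pytest.raises(ValueError, match="missing years"):
            build_report(_mini_panels(values), {("r1", "wheat"): obs})
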