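"""Phi screening: contingency construction, the statistic, and the ranking."""

from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nof1diary import (
    ContingencyTable2x2,
    Diary,
    DiaryError,
    FactorEffect,
    SimulationScenario,
    TierThresholds,
    VariableDef,
    analyze,
    build_contingency,
    phi,
    phi_undefined_reason,
    simulate_diary,
)
from nof1diary.correlate import report_json, report_tsv


def _diary(factor_vals, outcome_vals, dates=None):
    n = len(factor_vals)
    if dates is None:
        dates = [dt.date(2020, 1, 1) + dt.timedelta(days=i) for i in range(n)]
    data = pd.DataFrame(
        {"sym": [float(v) if v is not None else np.nan for v in outcome_vals],
         "trig": [float(v) if v is not None else np.nan for v in factor_vals]},
        index=dates,
    )
    return Diary("s", [VariableDef("sym", "outcome"), VariableDef("trig", "factor")], data)


def expand_table(t: ContingencyTable2x2) -> tuple[np.ndarray, np.ndarray]:
    """The 0/1 vectors whose joint counts are ``t`` (oracle helper)."""
    f = [1] * (t.n11 + t.n10) + [0] * (t.n01 + t.n00)
    o = [1] * t.n11 + [0] * t.n10 + [1] * t.n01 + [0] * t.n00
    return np.array(f, dtype=float), np.array(o, dtype=float)


class TestBuildContingency:
    def test_lag0_pairs_same_days(self):
        # 4 consecutive days, factor=(1,1,0,0), outcome=(1,0,1,0):
        # pairs (1,1),(1,0),(0,1),(0,0) -> one in each cell
        t = build_contingency(_diary([1, 1, 0, 0], [1, 0, 1, 0]), "sym", "trig", 0)
        assert (t.n11, t.n10, t.n01, t.n00) == (1, 1, 1, 1)

    def test_lag1_pairs_next_day(self):
        # same series at lag 1: pairs (f_t, o_{t+1}) = (1,0),(1,1),(0,0)
        t = build_contingency(_diary([1, 1, 0, 0], [1, 0, 1, 0]), "sym", "trig", 1)
        assert (t.n11, t.n10, t.n01, t.n00) == (1, 1, 0, 1)

    def test_lag1_requires_consecutive_calendar_days(self):
        dates = [dt.date(2020, 1, 1), dt.date(2020, 1, 2), dt.date(2020, 1, 4)]
        t = build_contingency(_diary([1, 0, 1], [0, 1, 1], dates), "sym", "trig", 1)
        assert t.total == 1  # only the 1st->2nd pair; the gap kills 2nd->3rd
        assert t.n11 == 1

    def test_missing_values_dropped_pairwise(self):
        t0 = build_contingency(_diary([1, None, 0], [1, 1, None]), "sym", "trig", 0)
        assert t0.total == 1
        t1 = build_contingency(_diary([1, None, 0], [1, 1, None]), "sym", "trig", 1)
        assert (t1.n11, t1.n10, t1.n01, t1.n00) == (1, 0, 0, 0)

    def test_count_totals_at_each_lag(self):
        d = _diary([1, 0, 1, 0, 1, 1], [0, 1, 1, 0, 0, 1])
        assert build_contingency(d, "sym", "trig", 0).total == 6
        assert build_contingency(d, "sym", "trig", 1).total == 5

    def test_rejects_bad_roles_and_lags(self):
        d = _diary([1], [1])
        with pytest.raises(DiaryError):
            build_contingency(d, "trig", "sym", 0)
        with pytest.raises(DiaryError):
            build_contingency(d, "sym", "nope", 0)
        with pytest.raises(ValueError):
            build_contingency(d, "sym", "trig", 2)


class TestPhi:
    @pytest.mark.parametrize(
        "table, expected",
        [
            (ContingencyTable2x2(5, 0, 0, 5), 1.0),
            (ContingencyTable2x2(0, 5, 5, 0), -1.0),
            (ContingencyTable2x2(2, 2, 2, 2), 0.0),
            (ContingencyTable2x2(6, 2, 1, 5), 0.5774),  # Pearson of the expanded vectors
        ],
    )
    def test_known_values(self, table, expected):
        assert phi(table) == pytest.approx(expected, abs=5e-5)

    @pytest.mark.parametrize(
        "table, reason",
        [
            (ContingencyTable2x2(0, 0, 3, 4), "no variation in factor"),
            (ContingencyTable2x2(3, 0, 4, 0), "no variation in outcome"),
            (ContingencyTable2x2(0, 0, 0, 0), "empty table"),
        ],
    )
    def test_degenerate_tables_undefined_with_reason(self, table, reason):
        assert phi(table) is None
        assert phi_undefined_reason(table) == reason

    @given(st.tuples(*[st.integers(0, 40)] * 4))
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_matches_pearson_on_expanded_vectors(self, cells):
        table = ContingencyTable2x2(*cells)
        value = phi(table)
        if value is None:
            assert phi_undefined_reason(table) is not None
            return
        f, o = expand_table(table)
        assert value == pytest.approx(np.corrcoef(f, o)[0, 1], abs=1e-12)

    @given(st.tuples(*[st.integers(0, 30)] * 4))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_antisymmetric_under_factor_flip(self, cells):
        table = ContingencyTable2x2(*cells)
        flipped = ContingencyTable2x2(table.n01, table.n00, table.n11, table.n10)
        a, b = phi(table), phi(flipped)
        if a is None:
            assert b is None
        else:
            assert b == pytest.approx(-a, abs=1e-12)


class TestAnalyze:
    def test_short_diary_all_insufficient(self):
        results = analyze(_diary([1, 0], [0, 1]))
        assert results and all(r.tier == "insufficient" and r.phi is None for r in results)

    def test_true_lag1_factor_ranks_first(self):
        sc = SimulationScenario(
            n_days=60,
            base_rate=0.2,
            seed=42,
            factors=(
                FactorEffect("trigger", 0.5, lag=1, effect=0.5),
                FactorEffect("decoy", 0.5, lag=0, effect=0.0),
            ),
        )
        results = analyze(simulate_diary(sc))
        assert (results[0].factor, results[0].lag) == ("trigger", 1)

    def test_constant_factor_reports_reason(self):
        results = analyze(_diary([0, 0, 0, 0], [1, 0, 1, 0]))
        lag0 = next(r for r in results if r.lag == 0)
        assert lag0.phi is None and lag0.phi_reason == "no variation in factor"

    def test_undefined_phi_sorts_last(self):
        dates = [dt.date(2020, 1, 1) + dt.timedelta(days=i) for i in range(8)]
        data = pd.DataFrame(
            {
                "sym": [1.0, 0, 1, 0, 1, 0, 1, 0],
                "varies": [1.0, 0, 1, 0, 1, 1, 0, 0],
                "flat": [0.0] * 8,
            },
            index=dates,
        )
        d = Diary(
            "s",
            [VariableDef("sym", "outcome"), VariableDef("varies", "factor"), VariableDef("flat", "factor")],
            data,
        )
        results = analyze(d)
        defined = [r.phi is not None for r in results]
        assert defined == sorted(defined, reverse=True)

    def test_deterministic_report(self):
        d = simulate_diary(
            SimulationScenario(n_days=40, base_rate=0.3, seed=7, factors=(FactorEffect("f", 0.5),))
        )
        r1, r2 = analyze(d), analyze(d)
        assert report_json(r1) == report_json(r2)
        assert [(-abs(r.phi) if r.phi is not None else 1, r.n_days) for r in r1] == sorted(
            (-abs(r.phi) if r.phi is not None else 1, r.n_days) for r in r1
        )

    def test_no_factors_gives_empty_report(self):
        data = pd.DataFrame({"sym": [1.0, 0.0]}, index=[dt.date(2020, 1, 1), dt.date(2020, 1, 2)])
        d = Diary("s", [VariableDef("sym", "outcome")], data)
        assert analyze(d) == []

    def test_tiers_follow_pair_counts(self):
        th = TierThresholds()
        assert [th.tier(n) for n in (0, 2, 3, 13, 14, 29, 30, 200)] == [
            "insufficient", "insufficient", "low", "low",
            "moderate", "moderate", "high", "high",
        ]

    def test_bonferroni_attaches_capped_pvalues(self):
        d = _diary([1, 0, 1, 0, 1, 0], [1, 0, 1, 0, 1, 0])
        results = analyze(d, bonferroni=True)
        for r in results:
            assert r.p_value is not None
            assert r.p_adjusted == pytest.approx(min(1.0, r.p_value * len(results)))

    def test_tsv_report_shape(self):
        d = _diary([1, 0, 1, 0], [0, 1, 0, 1])
        tsv = report_tsv(analyze(d))
        lines = tsv.strip().split("\n")
        assert lines[0].split("\t")[:4] == ["outcome", "factor", "lag", "phi"]
        assert len(lines) == 3  # header + lag0 + lag1
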