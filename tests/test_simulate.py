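"""Simulator: presets, sampling model, determinism, and the power harness."""

from __future__ import annotations

import numpy as np
import pytest

from nof1diary import (
    DetectionCriterion,
    FactorEffect,
    SimulationScenario,
    analyze,
    estimate_power,
    map_frequency_category,
    simulate_diary,
)
from nof1diary.diary import diary_to_csv


class TestFrequencyPresets:
    @pytest.mark.parametrize(
        "category, expected",
        [
            ("weekly", 1 / 7),
            ("monthly", 1 / 30),
            ("every few months", 1 / 90),
            ("less", 1 / 240),
            ("multiple/day", 0.95),
            ("daily", 0.80),
            ("Multiple times/day", 0.95),  # printed-form alias
        ],
    )
    def test_presets(self, category, expected):
        assert map_frequency_category(category) == pytest.approx(expected)

    def test_unknown_category_errors(self):
        with pytest.raises(ValueError, match="unknown frequency category"):
            map_frequency_category("hourly")

    def test_category_usable_as_base_rate(self):
        d = simulate_diary(SimulationScenario(n_days=30, base_rate="weekly", seed=1))
        assert d.n_entries() == 30


class TestSimulateDiary:
    def test_zero_base_rate_no_factors_means_no_events(self):
        d = simulate_diary(SimulationScenario(n_days=50, base_rate=0.0, seed=3))
        assert d.data["outcome"].sum() == 0

    def test_full_adherence_logs_every_day(self):
        d = simulate_diary(SimulationScenario(n_days=100, base_rate=0.3, seed=4))
        assert d.n_entries() == 100
        assert (np.diff([dt.toordinal() for dt in d.dates]) == 1).all()

    def test_empirical_rate_within_binomial_bound(self):
        p = 0.3
        n = 5000
        d = simulate_diary(SimulationScenario(n_days=n, base_rate=p, seed=12345))
        assert abs(d.data["outcome"].mean() - p) <= 3 * np.sqrt(p * (1 - p) / n)

    def test_partial_adherence_drops_whole_days(self):
        sc = SimulationScenario(n_days=2000, base_rate=0.2, adherence=0.7, seed=9)
        d = simulate_diary(sc)
        frac = d.n_entries() / 2000
        assert abs(frac - 0.7) <= 3 * np.sqrt(0.7 * 0.3 / 2000)
        assert not d.data.isna().any().any()  # missingness = absent rows, not NaN cells

    def test_seed_determinism_byte_identical(self):
        sc = SimulationScenario(
            n_days=60,
            base_rate=0.25,
            adherence=0.8,
            seed=77,
            factors=(FactorEffect("f1", 0.4, 1, 0.3), FactorEffect("f2", 0.6, 0, 0.0)),
        )
        assert diary_to_csv(simulate_diary(sc)) == diary_to_csv(simulate_diary(sc))

    def test_different_seeds_differ(self):
        a = simulate_diary(SimulationScenario(n_days=60, base_rate=0.5, seed=1))
        b = simulate_diary(SimulationScenario(n_days=60, base_rate=0.5, seed=2))
        assert diary_to_csv(a) != diary_to_csv(b)

    def test_lag1_effect_raises_next_day_rate(self):
        sc = SimulationScenario(
            n_days=4000,
            base_rate=0.2,
            seed=31,
            factors=(FactorEffect("trigger", 0.5, lag=1, effect=0.4),),
        )
        d = simulate_diary(sc)
        x = d.data["trigger"].to_numpy()[:-1]
        y = d.data["outcome"].to_numpy()[1:]
        assert y[x == 1].mean() - y[x == 0].mean() == pytest.approx(0.4, abs=0.05)

    def test_odds_ratio_mode(self):
        sc = SimulationScenario(
            n_days=8000,
            base_rate=0.2,
            seed=8,
            effect_scale="odds_ratio",
            factors=(FactorEffect("f", 0.5, lag=0, effect=4.0),),
        )
        d = simulate_diary(sc)
        x = d.data["f"].to_numpy()
        y = d.data["outcome"].to_numpy()
        expected = (0.25 * 4) / (1 + 0.25 * 4)  # odds 0.25 * OR 4
        assert y[x == 1].mean() == pytest.approx(expected, abs=0.03)
        assert y[x == 0].mean() == pytest.approx(0.2, abs=0.03)

    def test_intervention_phase_recorded_and_exposure_removed(self):
        sc = SimulationScenario(
            n_days=40,
            base_rate=0.2,
            seed=6,
            factors=(FactorEffect("f", 0.9, 0, 0.3),),
            intervention_start=20,
            intervention_removes=("f",),
        )
        d = simulate_diary(sc)
        assert [s.label for s in d.phases] == ["baseline", "intervention"]
        assert d.data["f"].to_numpy()[20:].sum() == 0

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_days=0, base_rate=0.2),
            dict(n_days=10, base_rate=1.5),
            dict(n_days=10, base_rate=0.2, adherence=0.0),
            dict(n_days=10, base_rate=0.8, factors=(FactorEffect("f", 0.5, 0, 0.5),)),
            dict(n_days=10, base_rate=0.2, factors=(FactorEffect("f", 0.5, 0, 0.1),),
                 intervention_start=10),
        ],
    )
    def test_invalid_scenarios_rejected_before_sampling(self, kwargs):
        with pytest.raises(ValueError):
            SimulationScenario(seed=0, **kwargs)


class TestPowerHarness:
    def test_effect_size_increases_detection(self):
        crit = DetectionCriterion("trigger", lag=1)
        rates = []
        for effect in (0.0, 0.4):
            sc = SimulationScenario(
                n_days=90,
                base_rate=0.2,
                seed=314,
                factors=(FactorEffect("trigger", 0.5, lag=1, effect=effect),),
            )
            rates.append(estimate_power(sc, 150, crit).detect_rate)
        assert rates[1] > rates[0]

    def test_mc_se_formula(self):
        sc = SimulationScenario(
            n_days=30, base_rate=0.2, seed=1, factors=(FactorEffect("t", 0.5, 1, 0.4),)
        )
        est = estimate_power(sc, 100, DetectionCriterion("t", lag=1))
        assert est.mc_se == pytest.approx(
            np.sqrt(est.detect_rate * (1 - est.detect_rate) / 100)
        )

    def test_power_estimate_reproducible(self):
        sc = SimulationScenario(
            n_days=60, base_rate=0.2, seed=99, factors=(FactorEffect("t", 0.5, 1, 0.3),)
        )
        crit = DetectionCriterion("t", lag=1)
        assert estimate_power(sc, 120, crit).detect_rate == estimate_power(sc, 120, crit).detect_rate

    def test_unknown_factor_in_criterion_errors(self):
        sc = SimulationScenario(
            n_days=30, base_rate=0.2, seed=2, factors=(FactorEffect("t", 0.5, 1, 0.2),)
        )
        with pytest.raises(ValueError, match="unknown factor"):
            estimate_power(sc, 100, DetectionCriterion("ghost", lag=1))

    def test_too_few_reps_rejected(self):
        sc = SimulationScenario(
            n_days=30, base_rate=0.2, seed=2, factors=(FactorEffect("t", 0.5, 1, 0.2),)
        )
        with pytest.raises(ValueError, match="n_reps"):
            estimate_power(sc, 50, DetectionCriterion("t", lag=1))

    def test_lag_identification_mean_phi(self):
        # across replicates, screening at the true lag beats the wrong lag
        sc = SimulationScenario(
            n_days=200,
            base_rate=0.2,
            seed=424,
            factors=(FactorEffect("trigger", 0.5, lag=1, effect=0.4),),
        )
        ss = np.random.SeedSequence(sc.seed)
        lag1, lag0 = [], []
        for child in ss.spawn(60):
            results = analyze(simulate_diary(sc, rng=np.random.default_rng(child)))
            by_lag = {r.lag: r.phi for r in results if r.factor == "trigger"}
            lag1.append(by_lag[1])
            lag0.append(by_lag[0])
        assert np.mean(lag1) > np.mean(lag0) + 0.2
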