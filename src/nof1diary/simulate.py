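"""Synthetic diary generation and power / type-I-error estimation.

The generator emulates the data a daily symptom tracker would collect: a
Bernoulli event series for the outcome whose daily probability is shifted
by same-day and previous-day trigger exposures, with completely-at-random
missed days.  Its base-rate presets mirror the recurrence-frequency
spectrum reported by prospective users of such trackers, where the bulk of
conditions recur daily or multiple times per day and only a few percent
recur monthly or less (see :data:`FREQUENCY_PRESETS`).

Model, day ``t`` (0-based), with exposures ``x_f(t) ~ Bernoulli(q_f)``
independent across factors and days::

    P(outcome on day t) = clip( base_rate + sum_f  delta_f * x_f(t - lag_f) , 0, 1)

Effects combine additively on the probability scale (risk differences);
an odds-ratio mode multiplies the baseline odds by ``OR_f`` per exposed
factor instead.  A day is logged with probability ``adherence``; an
unlogged day is absent from the diary entirely.  All draws flow from the
scenario seed, so a scenario is reproducible byte-for-byte.

An optional intervention phase can be simulated by forcing chosen factors
to zero exposure from a given day on, which is what a subject does when
they act on a suspected trigger.

The power harness replays a scenario many times, runs the screening
analysis on each replicate, and reports the fraction of replicates in
which a detection criterion flags the true factor at its true lag.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from math import sqrt

import numpy as np
import pandas as pd

from .correlate import TIERS, TierThresholds, analyze
from .diary import BASELINE, INTERVENTION, Diary, PhaseSpan, VariableDef

__all__ = [
    "FREQUENCY_PRESETS",
    "map_frequency_category",
    "FactorEffect",
    "SimulationScenario",
    "DetectionCriterion",
    "PowerEstimate",
    "simulate_diary",
    "estimate_power",
    "calibrate_phi_threshold",
]

#: Daily event probability presets for the recurrence-frequency categories a
#: tracker's users typically report.  "multiple/day" collapses within-day
#: multiplicity onto the daily-binary scale as a near-saturated probability —
#: deliberately so: a diary that is 1 almost every day carries almost no
#: contrast, and the harness should surface how hard detection is there.
#: The rarer categories are one event per nominal recurrence interval.
FREQUENCY_PRESETS: dict[str, float] = {
    "multiple/day": 0.95,
    "daily": 0.80,
    "weekly": 1.0 / 7.0,
    "monthly": 1.0 / 30.0,
    "every few months": 1.0 / 90.0,
    "less": 1.0 / 240.0,
}

_CATEGORY_ALIASES = {
    "multiple times/day": "multiple/day",
    "multiple times a day": "multiple/day",
    "less than every few months": "less",
}


def map_frequency_category(category: str) -> float:
    """Daily outcome probability for a recurrence-frequency category."""
    key = category.strip().lower()
    key = _CATEGORY_ALIASES.get(key, key)
    try:
        return FREQUENCY_PRESETS[key]
    except KeyError:
        raise ValueError(
            f"unknown frequency category {category!r}; expected one of {sorted(FREQUENCY_PRESETS)}"
        ) from None


@dataclass(frozen=True)
class FactorEffect:
    """A simulated trigger: exposure frequency and its effect on the outcome.

    ``effect`` is a risk difference added to the outcome probability on the
    affected day (or an odds ratio in the scenario's odds-ratio mode);
    ``lag`` 0 means same-day action, 1 means the exposure acts on the next
    day.
    """

    name: str
    exposure_prob: float
    lag: int = 0
    effect: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.exposure_prob <= 1.0:
            raise ValueError(f"factor {self.name!r}: exposure_prob must be in [0,1]")
        if self.lag not in (0, 1):
            raise ValueError(f"factor {self.name!r}: lag must be 0 or 1")


@dataclass(frozen=True)
class SimulationScenario:
    """Everything needed to draw one synthetic diary deterministically."""

    n_days: int
    base_rate: float | str  # probability, or a frequency-category name
    factors: tuple[FactorEffect, ...] = ()
    adherence: float = 1.0
    seed: int = 0
    effect_scale: str = "risk_difference"  # or "odds_ratio"
    outcome_name: str = "outcome"
    subject_id: str = "sim"
    start_date: dt.date = dt.date(2020, 1, 1)
    #: 0-based day index at which the intervention phase starts (None: no
    #: intervention phase).
    intervention_start: int | None = None
    #: factor names whose exposure is forced to 0 from intervention_start on.
    intervention_removes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "factors", tuple(self.factors))
        object.__setattr__(self, "intervention_removes", tuple(self.intervention_removes))
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        p0 = self.resolved_base_rate()
        if not 0.0 <= p0 <= 1.0:
            raise ValueError(f"base_rate {p0} outside [0,1]")
        if not 0.0 < self.adherence <= 1.0:
            raise ValueError("adherence must be in (0,1]")
        if self.effect_scale not in ("risk_difference", "odds_ratio"):
            raise ValueError("effect_scale must be 'risk_difference' or 'odds_ratio'")
        names = [f.name for f in self.factors]
        if len(set(names)) != len(names):
            raise ValueError("duplicate factor names")
        for f in self.factors:
            if self.effect_scale == "risk_difference":
                if not 0.0 <= p0 + f.effect <= 1.0:
                    raise ValueError(
                        f"factor {f.name!r}: base_rate + risk_difference = {p0 + f.effect} outside [0,1]"
                    )
            elif f.effect <= 0.0:
                raise ValueError(f"factor {f.name!r}: odds ratio must be positive")
        if self.intervention_start is not None and not 0 < self.intervention_start < self.n_days:
            raise ValueError("intervention_start must fall strictly inside the horizon")
        unknown = set(self.intervention_removes) - set(names)
        if unknown:
            raise ValueError(f"intervention_removes names unknown factors {sorted(unknown)}")

    def resolved_base_rate(self) -> float:
        if isinstance(self.base_rate, str):
            return map_frequency_category(self.base_rate)
        return float(self.base_rate)


def simulate_diary(scenario: SimulationScenario, rng: np.random.Generator | None = None) -> Diary:
    """Draw one diary from ``scenario``.

    Draw order is fixed (exposures factor by factor, then outcomes, then
    the logging mask) so that a given ``(scenario, seed)`` always yields
    the identical diary.
    """
    sc = scenario
    if rng is None:
        rng = np.random.default_rng(sc.seed)
    n = sc.n_days
    p0 = sc.resolved_base_rate()

    exposures = np.empty((len(sc.factors), n), dtype=np.int64)
    for i, f in enumerate(sc.factors):
        exposures[i] = rng.random(n) < f.exposure_prob
    if sc.intervention_start is not None:
        for i, f in enumerate(sc.factors):
            if f.name in sc.intervention_removes:
                exposures[i, sc.intervention_start :] = 0

    if sc.effect_scale == "risk_difference":
        p = np.full(n, p0)
        for i, f in enumerate(sc.factors):
            shifted = exposures[i] if f.lag == 0 else np.concatenate(([0], exposures[i][:-1]))
            p += f.effect * shifted
        p = np.clip(p, 0.0, 1.0)
    else:
        odds0 = p0 / (1.0 - p0) if p0 < 1.0 else np.inf
        log_odds = np.full(n, np.log(odds0) if odds0 > 0 else -np.inf)
        for i, f in enumerate(sc.factors):
            shifted = exposures[i] if f.lag == 0 else np.concatenate(([0], exposures[i][:-1]))
            log_odds += np.log(f.effect) * shifted
        p = 1.0 / (1.0 + np.exp(-log_odds))
        p[np.isneginf(log_odds)] = 0.0

    outcome = (rng.random(n) < p).astype(np.int64)
    logged = rng.random(n) < sc.adherence if sc.adherence < 1.0 else np.ones(n, dtype=bool)

    dates = [sc.start_date + dt.timedelta(days=int(i)) for i in range(n)]
    cols = {sc.outcome_name: outcome.astype(float)}
    for i, f in enumerate(sc.factors):
        cols[f.name] = exposures[i].astype(float)
    data = pd.DataFrame(cols, index=dates).loc[np.asarray(logged)]

    variables = [VariableDef(sc.outcome_name, "outcome")] + [
        VariableDef(f.name, "factor") for f in sc.factors
    ]
    phases: list[PhaseSpan] = []
    if sc.intervention_start is not None:
        phases = [
            PhaseSpan(BASELINE, dates[0], dates[sc.intervention_start - 1]),
            PhaseSpan(INTERVENTION, dates[sc.intervention_start], dates[-1]),
        ]
    return Diary(sc.subject_id, variables, data, phases)


# ----------------------------------------------------------------------
# Power harness


@dataclass(frozen=True)
class DetectionCriterion:
    """Rule deciding whether one replicate counts as a detection.

    The true factor at ``lag`` is "detected" when its screened phi is
    defined, |phi| >= ``min_abs_phi``, its confidence tier is at least
    ``min_tier``, and (if ``require_top_rank``) it heads the ranking.
    """

    factor: str
    lag: int = 1
    min_abs_phi: float = 0.3
    min_tier: str = "moderate"
    require_top_rank: bool = True

    def __post_init__(self) -> None:
        if self.min_tier not in TIERS:
            raise ValueError(f"min_tier must be one of {TIERS}")
        if self.lag not in (0, 1):
            raise ValueError("lag must be 0 or 1")

    def detected(self, results) -> bool:
        match = [r for r in results if r.factor == self.factor and r.lag == self.lag]
        if not match:
            raise ValueError(f"criterion references unknown factor {self.factor!r} at lag {self.lag}")
        r = match[0]
        if r.phi is None or abs(r.phi) < self.min_abs_phi:
            return False
        if TIERS.index(r.tier) < TIERS.index(self.min_tier):
            return False
        return (not self.require_top_rank) or results[0] is r

    def describe(self) -> str:
        parts = [f"|phi| >= {self.min_abs_phi:g}", f"tier >= {self.min_tier}"]
        if self.require_top_rank:
            parts.append("top rank")
        return f"{self.factor}@lag{self.lag}: " + ", ".join(parts)


@dataclass(frozen=True)
class PowerEstimate:
    scenario: SimulationScenario
    n_reps: int
    criterion: DetectionCriterion
    detect_rate: float

    @property
    def mc_se(self) -> float:
        return sqrt(self.detect_rate * (1.0 - self.detect_rate) / self.n_reps)

    def to_dict(self) -> dict:
        return {
            "criterion": self.criterion.describe(),
            "n_reps": self.n_reps,
            "detect_rate": self.detect_rate,
            "mc_se": self.mc_se,
        }


def _replicate_rngs(seed: int, n_reps: int) -> list[np.random.Generator]:
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(s) for s in ss.spawn(n_reps)]


def estimate_power(
    scenario: SimulationScenario,
    n_reps: int,
    criterion: DetectionCriterion,
    thresholds: TierThresholds = TierThresholds(),
) -> PowerEstimate:
    """Fraction of replicates in which the screening flags the true factor.

    Replicate streams are spawned from ``scenario.seed``, so the estimate
    is reproducible and distinct scenarios with the same seed still share
    no draws with each other's replicates.
    """
    if n_reps < 100:
        raise ValueError("n_reps must be >= 100")
    hits = 0
    for rng in _replicate_rngs(scenario.seed, n_reps):
        results = analyze(simulate_diary(scenario, rng=rng), thresholds=thresholds)
        hits += criterion.detected(results)
    return PowerEstimate(scenario, n_reps, criterion, hits / n_reps)


def calibrate_phi_threshold(
    scenario: SimulationScenario,
    factor: str,
    lag: int,
    alpha: float,
    n_reps: int,
    seed: int,
    thresholds: TierThresholds = TierThresholds(),
) -> float:
    """Empirical |phi| threshold with type-I rate ``alpha`` under ``scenario``.

    Simulates ``n_reps`` diaries from ``scenario`` (which should be a null
    scenario for the named factor), collects |phi| for that factor at the
    given lag (0 when undefined), and returns the upper ``alpha`` quantile.
    Use a ``seed`` distinct from any later evaluation run.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0,1)")
    stats = []
    for rng in _replicate_rngs(seed, n_reps):
        results = analyze(simulate_diary(scenario, rng=rng), thresholds=thresholds)
        match = [r for r in results if r.factor == factor and r.lag == lag]
        if not match:
            raise ValueError(f"unknown factor {factor!r} at lag {lag}")
        r = match[0]
        stats.append(0.0 if r.phi is None else abs(r.phi))
    return float(np.quantile(stats, 1.0 - alpha, method="higher"))
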