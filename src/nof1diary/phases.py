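"""Hypothesis testing: baseline vs. intervention recurrence comparison.

After the screening stage suggests a candidate trigger, the subject adopts
a lifestyle modification and keeps logging.  This module closes the loop:
it compares the outcome's event rate per logged day between the baseline
and intervention phases with a two-sided exact test of proportions, and
bundles the screening ranking and the phase comparison into one report
representing a full N-of-1 cycle.

The unit of analysis is the logged day (episode yes/no).  Unlogged days
are excluded from denominators, never imputed, and the phase boundary is
taken literally — no washout window is modelled.
"""

from __future__ import annotations

from dataclasses import dataclass

from .correlate import TierThresholds, analyze
from .diary import BASELINE, INTERVENTION, Diary, DiaryError, slice_phase
from .exact import fisher_exact_2x2

__all__ = ["PhaseComparison", "compare_phases", "summarize_loop"]


@dataclass(frozen=True)
class PhaseComparison:
    """Baseline vs. intervention event rates for one outcome."""

    outcome: str
    baseline_days: int
    baseline_events: int
    intervention_days: int
    intervention_events: int
    p_two_sided: float

    @property
    def baseline_rate(self) -> float:
        return self.baseline_events / self.baseline_days

    @property
    def intervention_rate(self) -> float:
        return self.intervention_events / self.intervention_days

    @property
    def rate_difference(self) -> float:
        return self.intervention_rate - self.baseline_rate

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "baseline_days": self.baseline_days,
            "baseline_events": self.baseline_events,
            "baseline_rate": self.baseline_rate,
            "intervention_days": self.intervention_days,
            "intervention_events": self.intervention_events,
            "intervention_rate": self.intervention_rate,
            "rate_difference": self.rate_difference,
            "p_two_sided": self.p_two_sided,
        }


def _phase_counts(diary: Diary, outcome: str, label: str) -> tuple[int, int]:
    sub = slice_phase(diary, label)
    col = sub.data[outcome]
    logged = col.notna()
    return int(logged.sum()), int((col == 1.0).sum())


def compare_phases(diary: Diary, outcome: str | None = None) -> PhaseComparison:
    """Exact-test comparison of the outcome's daily event rate across phases.

    ``outcome`` defaults to the diary's sole outcome.  Only days on which
    the outcome was actually logged enter either denominator.  The
    two-sided p comes from the exact test on the phase-by-event 2x2 table.
    """
    if outcome is None:
        if len(diary.outcomes) != 1:
            raise DiaryError("diary has multiple outcomes; name one explicitly")
        outcome = diary.outcomes[0]
    elif diary.role_of(outcome) != "outcome":
        raise DiaryError(f"{outcome!r} does not have role=outcome")

    b_days, b_events = _phase_counts(diary, outcome, BASELINE)
    i_days, i_events = _phase_counts(diary, outcome, INTERVENTION)
    for label, days in ((BASELINE, b_days), (INTERVENTION, i_days)):
        if days == 0:
            raise DiaryError(f"phase has no data: no logged {outcome!r} days in {label} phase")

    p = fisher_exact_2x2([[b_events, b_days - b_events], [i_events, i_days - i_events]])
    return PhaseComparison(
        outcome=outcome,
        baseline_days=b_days,
        baseline_events=b_events,
        intervention_days=i_days,
        intervention_events=i_events,
        p_two_sided=p,
    )


def summarize_loop(
    diary: Diary,
    outcome: str | None = None,
    thresholds: TierThresholds = TierThresholds(),
) -> dict:
    """One full N-of-1 cycle as a JSON-ready report.

    Always contains the screening ranking computed on the baseline slice
    (``associations``); when an intervention span with logged outcome data
    exists, also the baseline-vs-intervention ``phase_comparison``.
    """
    baseline = slice_phase(diary, BASELINE)
    report: dict = {
        "subject_id": diary.subject_id,
        "associations": [r.to_dict() for r in analyze(baseline, thresholds=thresholds)],
    }
    if diary.has_phase(INTERVENTION):
        outcomes = [outcome] if outcome is not None else diary.outcomes
        comparisons = []
        for o in outcomes:
            try:
                comparisons.append(compare_phases(diary, o).to_dict())
            except DiaryError as exc:
                comparisons.append({"outcome": o, "error": str(exc)})
        report["phase_comparison"] = comparisons[0] if outcome is not None else comparisons
    return report
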