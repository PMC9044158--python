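"""Feasibility-survey proportion reporting and across-category exact tests.

The pilot deployment of the tracker enrolled 180 participants; this module
packages the study's published summary counts as fixtures — demographics,
the conditions participants chose to track, recurrence frequencies,
technology-use habits, and follow-up/adoption broken down by demographic
category — and recomputes every printed percentage and the follow-up
association p-values from the raw counts.

Percentages are rounded half-away-from-zero (the convention the printed
values follow; banker's rounding would disagree on exact halves such as
62.5 -> 63).  Each fixture stores the percentage exactly as printed; one
printed cell is internally inconsistent with its stated denominator and is
flagged in :data:`KNOWN_DISCREPANCIES` rather than silently corrected.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

from .exact import ContingencyTableRxC, fisher_exact_rxc

__all__ = [
    "CategoryCount",
    "CountFixture",
    "FollowupRow",
    "FollowupFixture",
    "FIXTURES",
    "KNOWN_DISCREPANCIES",
    "proportion",
    "category_share",
    "followup_association",
    "render_fixture",
]


def proportion(numerator: int, denominator: int, decimals: int = 1) -> str:
    """``100 * numerator / denominator`` rounded half-away-from-zero.

    ``decimals=1`` gives the usual one-decimal percentage string;
    ``decimals=0`` the integer-precision form some summaries print.
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= numerator <= denominator:
        raise ValueError("numerator must be between 0 and denominator")
    scale = 10**decimals
    x = Fraction(100 * numerator * scale, denominator)
    whole, rem = divmod(x.numerator, x.denominator)
    if 2 * rem >= x.denominator:  # half rounds away from zero (values are >= 0)
        whole += 1
    if decimals == 0:
        return str(whole)
    s = str(whole).rjust(decimals + 1, "0")
    return f"{s[:-decimals]}.{s[-decimals:]}"


# ----------------------------------------------------------------------
# Fixture types


@dataclass(frozen=True)
class CategoryCount:
    label: str
    count: int
    printed_pct: str  # the percentage as printed in the study report
    decimals: int | None = None  # per-cell precision override (e.g. a bare "0")


@dataclass(frozen=True)
class CountFixture:
    """A labelled count vector with a stated denominator."""

    name: str
    n: int
    rows: tuple[CategoryCount, ...]
    source: str
    decimals: int = 1

    def labels(self) -> list[str]:
        return [r.label for r in self.rows]

    def recomputed_pct(self, label: str) -> str:
        for r in self.rows:
            if r.label == label:
                d = self.decimals if r.decimals is None else r.decimals
                return proportion(r.count, self.n, d)
        raise KeyError(f"unknown label {label!r} in fixture {self.name!r}")


@dataclass(frozen=True)
class FollowupRow:
    label: str
    completed: int
    total: int
    printed_pct: str


@dataclass(frozen=True)
class FollowupFixture:
    """Completed/total counts per category with the printed block p-value."""

    name: str
    rows: tuple[FollowupRow, ...]
    printed_p: str
    source: str
    decimals: int = 0

    def labels(self) -> list[str]:
        return [r.label for r in self.rows]

    def table(self) -> ContingencyTableRxC:
        return ContingencyTableRxC.from_rows(
            [
                [r.completed for r in self.rows],
                [r.total - r.completed for r in self.rows],
            ],
            row_labels=("completed", "not completed"),
            col_labels=tuple(self.labels()),
        )


def _count_fixture(name, n, source, rows, decimals=1):
    return CountFixture(
        name, n, tuple(CategoryCount(*row) for row in rows), source, decimals
    )


def _followup_fixture(name, source, p, rows):
    return FollowupFixture(
        name, tuple(FollowupRow(lbl, c, t, pct) for lbl, c, t, pct in rows), p, source
    )


# ----------------------------------------------------------------------
# Transcribed study counts.  `printed_pct` fields are verbatim from the
# published report; tests recompute each one from the raw counts.

FIXTURES: dict[str, CountFixture | FollowupFixture] = {}


def _register(f) -> None:
    FIXTURES[f.name] = f


_register(_count_fixture(
    "demographics_age", 180, "pre-use survey: age categories",
    [
        ("under 30", 38, "21.1"),
        ("31-45", 80, "44.4"),
        ("46-55", 32, "17.8"),
        ("56-65", 22, "12.2"),
        ("66-75", 8, "4.4"),
        ("over 75", 0, "0", 0),
    ],
))
_register(_count_fixture(
    "demographics_education", 177, "pre-use survey: education categories",
    [
        ("grade school only", 1, "0.6"),
        ("high school diploma/GED", 5, "2.8"),
        ("some college", 50, "28.2"),
        ("college degree", 66, "37.3"),
        ("master's degree", 48, "27.1"),
        ("doctorate degree", 7, "3.9"),
    ],
))
_register(_count_fixture(
    "demographics_race", 180, "pre-use survey: race categories",
    [
        ("White", 144, "80.0"),
        ("African American", 14, "7.8"),
        ("Asian", 9, "5.0"),
        ("American Indian or Alaskan Native", 5, "2.8"),
        ("more than 1/unknown", 8, "4.4"),
    ],
))
_register(_count_fixture(
    "demographics_ethnicity", 180, "pre-use survey: ethnicity categories",
    [
        ("Hispanic/Latino", 17, "9.4"),
        ("not Hispanic/Latino", 161, "89.4"),
        ("unknown", 2, "1.1"),
    ],
))
_register(_count_fixture(
    "conditions", 212, "pre-use survey: condition groups chosen for tracking (212 across 180 users)",
    [
        ("chronic pain", 80, "37.7"),
        ("headaches", 36, "17.0"),
        ("gastrointestinal symptoms", 17, "8.0"),
        ("depression", 15, "7.1"),
        ("anxiety", 12, "5.7"),
        ("palpitations", 7, "3.3"),
        ("hypertension", 7, "3.3"),
        ("dizziness", 5, "2.4"),
        ("other", 33, "15.6"),
    ],
))
_register(_count_fixture(
    "recurrence", 180, "pre-use survey: recurrence frequency of the tracked condition",
    [
        ("multiple/day", 65, "36.1"),
        ("daily", 75, "41.7"),
        ("weekly", 29, "16.1"),
        ("monthly", 6, "3.3"),
        ("every few months", 3, "1.7"),
        ("less", 2, "1.1"),
    ],
))
_register(_count_fixture(
    "usage", 103, "post-use survey: usage and adoption among follow-up completers",
    [
        ("used app full 3 months", 73, "70.9"),
        ("likely to reuse", 27, "26.2"),
        ("unlikely to reuse without modifications", 58, "56.3"),
        ("missed >50% of days", 3, "2.9"),
        ("missed <5% of days", 22, "21.4"),
    ],
))
_register(_count_fixture(
    "stopped_early", 16, "post-use survey: duration of use among early stoppers",
    [
        ("2 months", 2, "13"),
        ("1 month", 5, "31"),
        ("less than 1 month", 9, "56"),
    ],
    decimals=0,
))
_register(_count_fixture(
    "review_habits", 22, "post-use survey: data-review cadence among near-complete loggers",
    [
        ("weekly or every few weeks", 13, "59"),
        ("daily", 3, "14"),
    ],
    decimals=0,
))
_register(_count_fixture(
    "followup", 180, "study flow: post-use survey completion",
    [("completed follow-up", 103, "57.2")],
))
_register(_count_fixture(
    "weighing", 180, "pre-use survey: self-weighing frequency",
    [
        ("daily", 28, "15.6"),
        ("at least weekly", 58, "32.2"),
        ("monthly", 42, "23.3"),
        ("rarely or never", 52, "28.9"),
    ],
))
_register(_count_fixture(
    "social_media", 180, "pre-use survey: social-media posting frequency",
    [
        ("multiple times a day", 49, "27.2"),
        ("daily", 54, "30.0"),
        ("weekly", 49, "27.2"),
        ("monthly", 12, "6.7"),
        ("rarely or never", 14, "7.8"),
        ("not on social media", 2, "1.1"),
    ],
))
_register(_count_fixture(
    "provider_messaging", 178, "pre-use survey: electronic communication with primary physician",
    [
        ("regularly", 64, "36.0"),
        ("rarely", 66, "37.1"),
        ("in person only", 13, "7.3"),
    ],
))
_register(_count_fixture(
    "pre_use_intent", 180, "pre-use survey: likelihood of using an app for self-management",
    [
        ("very likely", 74, "41.1"),
        ("somewhat likely", 63, "35.0"),
        ("unlikely", 6, "3.3"),
    ],
))
_register(_count_fixture(
    "intent_changers", 6, "post-use survey: answers of the 6 initially-unlikely users",
    [
        ("changed to neutral", 2, "33"),
        ("changed to somewhat likely", 4, "67"),
    ],
    decimals=0,
))

_register(_followup_fixture(
    "followup_by_age", "post-use survey completion by age category", ".87",
    [
        ("under 30", 19, 38, "50"),
        ("31-45", 46, 80, "58"),
        ("46-55", 20, 32, "63"),
        ("56-65", 13, 22, "59"),
        ("66-75", 5, 8, "63"),
    ],
))
_register(_followup_fixture(
    "followup_by_education", "post-use survey completion by education", ".04",
    [
        ("grade school only", 0, 4, "0"),
        ("high school diploma/GED", 1, 5, "20"),
        ("some college", 22, 50, "44"),
        ("college degree", 39, 66, "59"),
        ("master's degree", 34, 48, "71"),
        ("doctorate degree", 5, 7, "71"),
    ],
))
_register(_followup_fixture(
    "followup_by_race", "post-use survey completion by race", ".37",
    [
        ("Caucasian", 84, 144, "58"),
        ("African American", 9, 14, "64"),
        ("Asian", 2, 9, "22"),
        ("American Indian or Alaskan Native", 3, 5, "60"),
        ("more than 1/unknown", 5, 8, "63"),
    ],
))
_register(_followup_fixture(
    "followup_by_ethnicity", "post-use survey completion by ethnicity", ">.99",
    [
        ("Hispanic/Latino", 10, 17, "59"),
        ("not Hispanic/Latino", 92, 161, "57"),
        ("unknown", 1, 2, "50"),
    ],
))
_register(_followup_fixture(
    "adoption_by_age", "3-month adoption by age category among completers", ".37",
    [
        ("under 30", 13, 19, "68"),
        ("31-45", 29, 46, "63"),
        ("46-55", 15, 20, "75"),
        ("56-65", 11, 13, "85"),
        ("66-75", 5, 7, "71"),
    ],
))
_register(_followup_fixture(
    "adoption_by_education", "3-month adoption by education among completers", ".83",
    [
        ("high school diploma/GED", 1, 1, "100"),
        ("some college", 17, 22, "77"),
        ("college degree", 28, 39, "72"),
        ("master's degree", 22, 34, "65"),
        ("doctorate degree", 3, 5, "60"),
    ],
))
_register(_followup_fixture(
    "adoption_by_race", "3-month adoption by race among completers", ".05",
    [
        ("Caucasian", 60, 84, "71"),
        ("African American", 8, 9, "89"),
        ("Asian", 2, 2, "100"),
        ("American Indian or Alaskan Native", 3, 3, "100"),
        ("more than 1/unknown", 3, 5, "60"),
    ],
))
_register(_followup_fixture(
    "adoption_by_ethnicity", "3-month adoption by ethnicity among completers", ">.99",
    [
        ("Hispanic/Latino", 7, 10, "70"),
        ("not Hispanic/Latino", 65, 92, "71"),
        ("unknown", 1, 1, "100"),
    ],
))

#: (fixture, label) cells whose printed percentage cannot be reproduced from
#: the printed count and the block's stated denominator under any standard
#: rounding; preserved verbatim and flagged instead of corrected.
#: 7/177 = 3.95...% rounds to 4.0, yet 3.9 is printed (it matches n=180).
KNOWN_DISCREPANCIES: dict[tuple[str, str], str] = {
    ("demographics_education", "doctorate degree"): (
        "printed 3.9 but 7/177 recomputes to 4.0; the printed value matches the "
        "cohort denominator 180 rather than the education block's stated n=177"
    ),
}


# ----------------------------------------------------------------------
# Operations


def category_share(fixture: CountFixture | str, labels) -> str:
    """Percentage of the fixture's total held by the named labels combined."""
    if isinstance(fixture, str):
        fixture = FIXTURES[fixture]
    if not isinstance(fixture, CountFixture):
        raise TypeError("category_share needs a count fixture")
    wanted = list(labels)
    known = {r.label: r.count for r in fixture.rows}
    unknown = [l for l in wanted if l not in known]
    if unknown:
        raise KeyError(f"unknown label(s) {unknown} in fixture {fixture.name!r}")
    return proportion(sum(known[l] for l in wanted), fixture.n, fixture.decimals)


def followup_association(
    fixture: FollowupFixture | str,
    max_enumeration: int = 100_000,
    mc_reps: int = 100_000,
    seed: int | None = 0,
) -> tuple[float, str]:
    """Exact-test p for homogeneity of completion across the fixture's categories."""
    if isinstance(fixture, str):
        fixture = FIXTURES[fixture]
    if not isinstance(fixture, FollowupFixture):
        raise TypeError("followup_association needs a completed/total fixture")
    return fisher_exact_rxc(
        fixture.table(), max_enumeration=max_enumeration, mc_reps=mc_reps, seed=seed
    )


def render_fixture(fixture: CountFixture | FollowupFixture, with_p: bool = True, seed: int | None = 0) -> str:
    """Human-readable recomputation of a fixture (TSV)."""
    lines = [f"# {fixture.name}: {fixture.source}"]
    if isinstance(fixture, CountFixture):
        lines.append("label\tcount\tn\tpct\tprinted_pct")
        for r in fixture.rows:
            pct = fixture.recomputed_pct(r.label)
            lines.append(f"{r.label}\t{r.count}\t{fixture.n}\t{pct}\t{r.printed_pct}")
    else:
        lines.append("label\tcompleted\ttotal\tpct\tprinted_pct")
        for r in fixture.rows:
            pct = proportion(r.completed, r.total, fixture.decimals)
            lines.append(f"{r.label}\t{r.completed}\t{r.total}\t{pct}\t{r.printed_pct}")
        if with_p:
            p, method = followup_association(fixture, seed=seed)
            lines.append(f"# exact test p = {p:.4f} ({method}); printed: {fixture.printed_p}")
    return "\n".join(lines) + "\n"
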