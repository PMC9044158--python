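"""Hypothesis generation: phi-coefficient screening of factors against outcomes.

Each candidate trigger (factor) is screened against each outcome at two
time offsets:

* lag 0 — the factor on day *t* paired with the outcome on the same day;
* lag 1 — the factor on day *t* paired with the outcome on day *t+1*,
  counted only when the two dates are consecutive calendar days, so that a
  gap in logging never fabricates a next-day pair.

Pairs with either value missing are dropped (pairwise-complete).  The
association strength is the phi coefficient of the resulting 2x2 table,

    phi = (n11*n00 - n10*n01) / sqrt(r1 * r0 * c1 * c0)

with ``r``/``c`` the row (factor) and column (outcome) marginals — exactly
the Pearson correlation of the two underlying 0/1 series.  phi is undefined
whenever a marginal is zero (a constant series carries no correlation
information); that is reported as a machine-readable reason, never an
exception.

Because a handful of days cannot support a stable correlation, each result
carries a qualitative confidence tier driven by the number of complete
pairs: ``insufficient`` (< 3, phi withheld), ``low`` (3-13), ``moderate``
(14-29), ``high`` (>= 30).  Screening starts at 3 complete pairs; precision
grows with diary length.  The thresholds are conventions of this package
and are configurable.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass

from .diary import Diary, DiaryError

__all__ = [
    "ContingencyTable2x2",
    "AssociationResult",
    "TierThresholds",
    "TIERS",
    "build_contingency",
    "phi",
    "phi_undefined_reason",
    "analyze",
    "report_tsv",
    "report_json",
]

#: Confidence tiers, weakest to strongest.
TIERS = ("insufficient", "low", "moderate", "high")


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Joint counts of factor presence (rows) by outcome presence (columns).

    ``n11`` counts days with factor present and outcome present, ``n10``
    factor present / outcome absent, ``n01`` factor absent / outcome
    present, ``n00`` neither.
    """

    n11: int
    n10: int
    n01: int
    n00: int

    def __post_init__(self) -> None:
        for k in ("n11", "n10", "n01", "n00"):
            v = getattr(self, k)
            if not isinstance(v, (int,)) or v < 0:
                raise ValueError(f"{k} must be a nonnegative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.n11 + self.n10 + self.n01 + self.n00

    @property
    def marginals(self) -> tuple[int, int, int, int]:
        """(r1, r0, c1, c0): factor-present/absent and outcome-present/absent totals."""
        return (
            self.n11 + self.n10,
            self.n01 + self.n00,
            self.n11 + self.n01,
            self.n10 + self.n00,
        )

    def as_rows(self) -> list[list[int]]:
        return [[self.n11, self.n10], [self.n01, self.n00]]


@dataclass(frozen=True)
class TierThresholds:
    """Minimum complete-pair counts for each tier above ``insufficient``."""

    low: int = 3
    moderate: int = 14
    high: int = 30

    def __post_init__(self) -> None:
        if not 0 < self.low <= self.moderate <= self.high:
            raise ValueError("tier thresholds must satisfy 0 < low <= moderate <= high")

    def tier(self, n_days: int) -> str:
        if n_days >= self.high:
            return "high"
        if n_days >= self.moderate:
            return "moderate"
        if n_days >= self.low:
            return "low"
        return "insufficient"


@dataclass(frozen=True)
class AssociationResult:
    """One screened (outcome, factor, lag) triple."""

    outcome: str
    factor: str
    lag: int
    phi: float | None
    phi_reason: str | None  # why phi is undefined, else None
    n_days: int
    table: ContingencyTable2x2
    tier: str
    p_value: float | None = None
    p_adjusted: float | None = None

    def to_dict(self) -> dict:
        d = {
            "outcome": self.outcome,
            "factor": self.factor,
            "lag": self.lag,
            "phi": None if self.phi is None else round(self.phi, 4),
            "phi_reason": self.phi_reason,
            "n_days": self.n_days,
            "n11": self.table.n11,
            "n10": self.table.n10,
            "n01": self.table.n01,
            "n00": self.table.n00,
            "tier": self.tier,
        }
        if self.p_value is not None:
            d["p_value"] = self.p_value
        if self.p_adjusted is not None:
            d["p_adjusted"] = self.p_adjusted
        return d


def build_contingency(diary: Diary, outcome: str, factor: str, lag: int) -> ContingencyTable2x2:
    """Count the factor-by-outcome 2x2 table at the given lag.

    At lag 0 a day contributes when both values are logged.  At lag 1 day
    *t*'s factor is paired with day *t+1*'s outcome only when the diary
    holds entries on both of those consecutive calendar days and both
    values are logged.
    """
    if diary.role_of(outcome) != "outcome":
        raise DiaryError(f"{outcome!r} does not have role=outcome")
    if diary.role_of(factor) != "factor":
        raise DiaryError(f"{factor!r} does not have role=factor")
    if lag not in (0, 1):
        raise ValueError(f"lag must be 0 or 1, got {lag}")

    f = diary.data[factor].to_numpy()
    o = diary.data[outcome].to_numpy()
    dates = diary.data.index

    pairs: list[tuple[float, float]] = []
    if lag == 0:
        pairs = [(fv, ov) for fv, ov in zip(f, o)]
    else:
        for i in range(len(dates) - 1):
            if (dates[i + 1] - dates[i]).days == 1:
                pairs.append((f[i], o[i + 1]))
    n = [[0, 0], [0, 0]]
    for fv, ov in pairs:
        if math.isnan(fv) or math.isnan(ov):
            continue
        n[int(fv)][int(ov)] += 1
    return ContingencyTable2x2(n11=n[1][1], n10=n[1][0], n01=n[0][1], n00=n[0][0])


def phi_undefined_reason(table: ContingencyTable2x2) -> str | None:
    """Machine-readable reason phi is undefined for ``table``, or None."""
    if table.total == 0:
        return "empty table"
    r1, r0, c1, c0 = table.marginals
    if r1 == 0 or r0 == 0:
        return "no variation in factor"
    if c1 == 0 or c0 == 0:
        return "no variation in outcome"
    return None


def phi(table: ContingencyTable2x2) -> float | None:
    """Phi coefficient of a 2x2 table; None when any marginal is zero."""
    if phi_undefined_reason(table) is not None:
        return None
    r1, r0, c1, c0 = table.marginals
    num = table.n11 * table.n00 - table.n10 * table.n01
    return num / math.sqrt(r1 * r0 * c1 * c0)


def _sort_key(r: AssociationResult) -> tuple:
    # defined phi first, |phi| desc, then larger n_days, then name, then lag
    if r.phi is None:
        return (1, 0.0, -r.n_days, r.factor, r.lag)
    return (0, -abs(r.phi), -r.n_days, r.factor, r.lag)


def analyze(
    diary: Diary,
    thresholds: TierThresholds = TierThresholds(),
    with_pvalues: bool = False,
    bonferroni: bool = False,
) -> list[AssociationResult]:
    """Screen every (outcome, factor) pair at lag 0 and lag 1.

    Returns one :class:`AssociationResult` per triple, ranked by |phi|
    descending (ties: larger pair count, then factor name, then lag);
    results with undefined phi sort last.  Fewer than ``thresholds.low``
    complete pairs yields tier ``insufficient`` with phi withheld.

    ``with_pvalues`` attaches a two-sided exact-test p per table (the
    default report mirrors an interactive tracker and surfaces raw
    correlations only); ``bonferroni`` additionally multiplies each p by
    the number of screened triples, capped at 1.
    """
    if bonferroni:
        with_pvalues = True
    results: list[AssociationResult] = []
    for outcome in diary.outcomes:
        for factor in diary.factors:
            for lag in (0, 1):
                table = build_contingency(diary, outcome, factor, lag)
                n_days = table.total
                tier = thresholds.tier(n_days)
                if tier == "insufficient":
                    value, reason = None, f"fewer than {thresholds.low} complete day pairs"
                else:
                    value, reason = phi(table), phi_undefined_reason(table)
                pval = None
                if with_pvalues:
                    from .exact import fisher_exact_2x2

                    pval = fisher_exact_2x2(table)
                results.append(
                    AssociationResult(
                        outcome=outcome,
                        factor=factor,
                        lag=lag,
                        phi=value,
                        phi_reason=reason,
                        n_days=n_days,
                        table=table,
                        tier=tier,
                        p_value=pval,
                    )
                )
    if bonferroni and results:
        m = len(results)
        results = [
            dataclasses.replace(r, p_adjusted=min(1.0, r.p_value * m) if r.p_value is not None else None)
            for r in results
        ]
    return sorted(results, key=_sort_key)


def report_tsv(results: list[AssociationResult]) -> str:
    """Tab-separated report, one screened triple per line, phi to 4 d.p."""
    cols = ["outcome", "factor", "lag", "phi", "n_days", "n11", "n10", "n01", "n00", "tier"]
    has_p = any(r.p_value is not None for r in results)
    if has_p:
        cols.append("p_value")
    has_adj = any(r.p_adjusted is not None for r in results)
    if has_adj:
        cols.append("p_adjusted")
    lines = ["\t".join(cols)]
    for r in results:
        row = [
            r.outcome,
            r.factor,
            str(r.lag),
            "NA" if r.phi is None else f"{r.phi:.4f}",
            str(r.n_days),
            str(r.table.n11),
            str(r.table.n10),
            str(r.table.n01),
            str(r.table.n00),
            r.tier,
        ]
        if has_p:
            row.append("NA" if r.p_value is None else f"{r.p_value:.4g}")
        if has_adj:
            row.append("NA" if r.p_adjusted is None else f"{r.p_adjusted:.4g}")
        lines.append("\t".join(row))
    return "\n".join(lines) + "\n"


def report_json(results: list[AssociationResult]) -> str:
    return json.dumps([r.to_dict() for r in results], indent=2) + "\n"
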