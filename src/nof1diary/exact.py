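"""Exact tests of proportions for small contingency tables.

Both tests condition on the observed margins and use the probability-
ordering ("exact") two-sided rule: the p-value is the total conditional
probability of every table, with the same margins, whose probability does
not exceed the observed table's.  This is the dominant convention for the
test (it is what R's ``fisher.test`` reports), as opposed to doubling a
one-sided tail.

For 2x2 tables the null distribution is hypergeometric in the single free
cell and the sum is taken over exact integer weights, so ties are resolved
exactly.  For larger R x C tables the conditional distribution is the
multivariate (Fisher-Yates) hypergeometric; the lattice of tables with the
observed margins is enumerated when small enough, and otherwise the
p-value is estimated by Monte Carlo over margin-preserving samples
(Patefield's algorithm via :func:`scipy.stats.random_table`), with the
add-one estimator ``(1 + #{P(sample) <= P(obs)}) / (reps + 1)``.

Probability comparisons in the float paths use a relative tie tolerance of
1e-7 so that enumeration order and log-domain arithmetic cannot flip a tie.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb, log
from typing import Iterator, Sequence

import numpy as np
from scipy import stats
from scipy.special import gammaln

__all__ = [
    "ContingencyTableRxC",
    "fisher_exact_2x2",
    "fisher_exact_rxc",
    "count_tables_with_margins",
]

#: Relative tolerance when comparing table probabilities for ties.
TIE_RTOL = 1e-7


@dataclass(frozen=True)
class ContingencyTableRxC:
    """An R x C table of nonnegative counts with optional axis labels."""

    counts: tuple[tuple[int, ...], ...]
    row_labels: tuple[str, ...] = ()
    col_labels: tuple[str, ...] = ()

    @classmethod
    def from_rows(
        cls,
        rows: Sequence[Sequence[int]],
        row_labels: Sequence[str] = (),
        col_labels: Sequence[str] = (),
    ) -> "ContingencyTableRxC":
        counts = tuple(tuple(int(c) for c in r) for r in rows)
        if len(counts) < 2 or any(len(r) != len(counts[0]) for r in counts) or len(counts[0]) < 2:
            raise ValueError("table must be at least 2x2 and rectangular")
        if any(c < 0 for r in counts for c in r):
            raise ValueError("counts must be nonnegative")
        if all(c == 0 for r in counts for c in r):
            raise ValueError("table must contain at least one positive count")
        if row_labels and len(row_labels) != len(counts):
            raise ValueError("row_labels length mismatch")
        if col_labels and len(col_labels) != len(counts[0]):
            raise ValueError("col_labels length mismatch")
        return cls(counts, tuple(row_labels), tuple(col_labels))

    @property
    def row_margins(self) -> tuple[int, ...]:
        return tuple(sum(r) for r in self.counts)

    @property
    def col_margins(self) -> tuple[int, ...]:
        return tuple(sum(c) for c in zip(*self.counts))

    @property
    def total(self) -> int:
        return sum(self.row_margins)


def _as_2x2(table) -> tuple[int, int, int, int]:
    if hasattr(table, "n11"):
        return table.n11, table.n10, table.n01, table.n00
    (a, b), (c, d) = table
    return int(a), int(b), int(c), int(d)


def fisher_exact_2x2(table) -> float:
    """Two-sided exact-test p-value for a 2x2 table.

    Accepts a :class:`~nof1diary.correlate.ContingencyTable2x2` or any
    2x2 nested sequence ``[[n11, n10], [n01, n00]]``.  A table with a zero
    margin admits only one configuration, so p = 1.
    """
    n11, n10, n01, n00 = _as_2x2(table)
    r1, r0 = n11 + n10, n01 + n00
    c1 = n11 + n01
    n = r1 + r0
    if r1 == 0 or r0 == 0 or c1 == 0 or c1 == n:
        return 1.0
    lo, hi = max(0, c1 - r0), min(r1, c1)
    # integer weights proportional to the hypergeometric pmf: exact tie handling
    weights = {k: comb(r1, k) * comb(r0, c1 - k) for k in range(lo, hi + 1)}
    w_obs = weights[n11]
    tail = sum(w for w in weights.values() if w <= w_obs)
    return min(1.0, tail / comb(n, c1))


# ----------------------------------------------------------------------
# R x C


def _enumerate_tables(
    row_margins: Sequence[int], col_margins: Sequence[int], limit: int | None = None
) -> Iterator[np.ndarray]:
    """Yield every nonnegative integer table with the given margins.

    Rows are filled recursively; the last row and last column are forced.
    If ``limit`` is given, raises ``OverflowError`` after yielding more
    than ``limit`` tables.
    """
    R, C = len(row_margins), len(col_margins)
    table = np.zeros((R, C), dtype=np.int64)
    remaining = np.asarray(col_margins, dtype=np.int64).copy()
    count = 0

    def fill_row(i: int) -> Iterator[np.ndarray]:
        nonlocal count
        if i == R - 1:
            if (remaining >= 0).all() and remaining.sum() == row_margins[i]:
                table[i, :] = remaining
                count += 1
                if limit is not None and count > limit:
                    raise OverflowError("enumeration limit exceeded")
                yield table
            return
        yield from fill_cell(i, 0, row_margins[i])

    def fill_cell(i: int, j: int, left: int) -> Iterator[np.ndarray]:
        if j == C - 1:
            if left <= remaining[j]:
                table[i, j] = left
                remaining[j] -= left
                yield from fill_row(i + 1)
                remaining[j] += left
            return
        # leave enough for the later columns of this row
        later_cap = int(remaining[j + 1 :].sum())
        lo = max(0, left - later_cap)
        hi = min(left, int(remaining[j]))
        for v in range(lo, hi + 1):
            table[i, j] = v
            remaining[j] -= v
            yield from fill_cell(i, j + 1, left - v)
            remaining[j] += v

    yield from fill_row(0)


def count_tables_with_margins(row_margins: Sequence[int], col_margins: Sequence[int]) -> int:
    """Number of nonnegative integer tables with the given margins.

    Dynamic program over rows: after each row the state is the vector of
    remaining column totals.
    """
    states = {tuple(int(c) for c in col_margins): 1}
    for r in row_margins[:-1]:
        nxt: dict[tuple[int, ...], int] = {}
        for cols, mult in states.items():
            for filled in _row_fills(cols, r):
                rem = tuple(c - f for c, f in zip(cols, filled))
                nxt[rem] = nxt.get(rem, 0) + mult
        states = nxt
    return sum(states.values())


def _row_fills(caps: tuple[int, ...], total: int) -> Iterator[tuple[int, ...]]:
    if len(caps) == 1:
        if total <= caps[0]:
            yield (total,)
        return
    later = sum(caps[1:])
    for v in range(max(0, total - later), min(total, caps[0]) + 1):
        for rest in _row_fills(caps[1:], total - v):
            yield (v,) + rest


def _log_table_prob(counts: np.ndarray, log_norm: float) -> float:
    """Log Fisher-Yates probability given precomputed margin/total term."""
    return float(log_norm - gammaln(counts + 1).sum())


def fisher_exact_rxc(
    table: ContingencyTableRxC | Sequence[Sequence[int]],
    max_enumeration: int = 100_000,
    mc_reps: int = 100_000,
    seed: int | None = 0,
) -> tuple[float, str]:
    """Two-sided exact-test p-value for an R x C table.

    Returns ``(p, method)`` with method ``"enumeration"`` when the lattice
    of margin-preserving tables has at most ``max_enumeration`` elements,
    else ``"monte_carlo"`` with ``mc_reps`` margin-preserving samples drawn
    with ``seed``.
    """
    if not isinstance(table, ContingencyTableRxC):
        table = ContingencyTableRxC.from_rows(table)
    rows = [r for r in table.counts if sum(r) > 0]
    cols_keep = [j for j in range(len(table.counts[0])) if sum(r[j] for r in table.counts) > 0]
    counts = np.asarray([[r[j] for j in cols_keep] for r in rows], dtype=np.int64)
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        return 1.0, "enumeration"  # a zero margin forces a single configuration

    rm = counts.sum(axis=1)
    cm = counts.sum(axis=0)
    n = int(counts.sum())
    log_norm = float(gammaln(rm + 1).sum() + gammaln(cm + 1).sum() - gammaln(n + 1))
    logp_obs = _log_table_prob(counts, log_norm)
    # relative tie tolerance on probabilities == additive tolerance on logs
    log_tol = log(1.0 + TIE_RTOL)

    # Lazily enumerate the lattice; bail out to Monte Carlo past the cap.
    try:
        tail = 0.0
        for t in _enumerate_tables(tuple(rm), tuple(cm), limit=max_enumeration):
            lp = _log_table_prob(t, log_norm)
            if lp <= logp_obs + log_tol:
                tail += np.exp(lp)
        return min(1.0, float(tail)), "enumeration"
    except OverflowError:
        pass

    if mc_reps < 1000:
        raise ValueError(f"Monte Carlo required for this table but mc_reps={mc_reps} < 1000")
    rng = np.random.default_rng(seed)
    dist = stats.random_table(rm, cm, seed=rng)
    samples = dist.rvs(mc_reps, method="patefield")
    logps = log_norm - gammaln(samples + 1).sum(axis=(-2, -1))
    hits = int(np.count_nonzero(logps <= logp_obs + log_tol))
    return (1.0 + hits) / (mc_reps + 1.0), "monte_carlo"
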