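"""Domain model for single-subject daily event diaries.

A diary records, for one subject, a date-ordered series of binary daily
observations: one or more *outcomes* (the recurrent condition — did an
episode occur today?) and zero or more *factors* (candidate lifestyle
triggers — was the subject exposed today?).  Calendar gaps are allowed and
mean "no entry that day", which is distinct from a logged 0: an unlogged
day carries no information, a 0 means the event or exposure did not occur.

Days are grouped into *phases*: a baseline observation phase and, after the
subject commits to a lifestyle modification, an intervention phase.  Any
entry that falls outside every declared phase span counts as baseline, so a
single-phase diary needs no phase bookkeeping at all.

CSV format
----------
One row per logged day, values ``0``/``1``/blank::

    #subject,s01
    #role,,outcome,factor
    #phase,baseline,2020-01-01,2020-01-31,
    #phase,intervention,2020-02-01,2020-02-29,cut caffeine
    date,phase,migraine,caffeine
    2020-01-01,baseline,1,0
    ...

The ``#``-directive lines and the ``phase`` column are optional on input.
Without a ``#role`` directive (or an explicit role mapping) the first value
column is taken as the outcome and the rest as factors.  :func:`write_diary`
always emits the directives so that ``read(write(d)) == d`` exactly.
"""

from __future__ import annotations

import csv
import datetime as dt
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BASELINE",
    "INTERVENTION",
    "PHASE_LABELS",
    "DiaryError",
    "VariableDef",
    "DayRecord",
    "PhaseSpan",
    "Diary",
    "read_diary",
    "write_diary",
    "slice_phase",
]

BASELINE = "baseline"
INTERVENTION = "intervention"
PHASE_LABELS = (BASELINE, INTERVENTION)

_ROLES = ("outcome", "factor")


class DiaryError(ValueError):
    """Raised for any diary domain violation (bad value, duplicate date, ...)."""


@dataclass(frozen=True)
class VariableDef:
    """A tracked variable: its column name and role (``outcome`` or ``factor``)."""

    name: str
    role: str

    def __post_init__(self) -> None:
        if self.role not in _ROLES:
            raise DiaryError(f"variable {self.name!r}: role must be one of {_ROLES}, got {self.role!r}")
        if not self.name or self.name in ("date", "phase") or self.name.startswith("#"):
            raise DiaryError(f"invalid variable name {self.name!r}")


@dataclass(frozen=True)
class DayRecord:
    """One logged day: a date plus a value in {0, 1, None} per variable."""

    date: dt.date
    values: Mapping[str, int | None]


@dataclass(frozen=True)
class PhaseSpan:
    """A contiguous, inclusive date range carrying a phase label."""

    label: str
    start: dt.date
    end: dt.date
    note: str = ""

    def __post_init__(self) -> None:
        if self.label not in PHASE_LABELS:
            raise DiaryError(f"unknown phase label {self.label!r}; expected one of {PHASE_LABELS}")
        if self.start > self.end:
            raise DiaryError(f"phase span {self.label}: start {self.start} after end {self.end}")

    def __contains__(self, date: dt.date) -> bool:
        return self.start <= date <= self.end


class Diary:
    """A subject's dated series of binary observations with phase labels.

    Parameters
    ----------
    subject_id:
        Opaque identifier; carried through reports.
    variables:
        Ordered variable definitions; at least one must have role ``outcome``.
    data:
        DataFrame indexed by strictly increasing ``datetime.date``, one float
        column per variable with values 0.0, 1.0 or NaN (missing).
    phases:
        Non-overlapping :class:`PhaseSpan` list.  Dates outside every span
        are baseline by default.
    """

    def __init__(
        self,
        subject_id: str,
        variables: Sequence[VariableDef],
        data: pd.DataFrame,
        phases: Sequence[PhaseSpan] = (),
    ) -> None:
        self.subject_id = str(subject_id)
        self.variables = list(variables)
        self.phases = list(phases)

        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise DiaryError("duplicate variable names")
        if not any(v.role == "outcome" for v in self.variables):
            raise DiaryError("diary must declare at least one outcome variable")
        if list(data.columns) != names:
            raise DiaryError("data columns must match variable names in order")

        data = data.astype(float)
        idx = list(data.index)
        for d in idx:
            if not isinstance(d, dt.date) or isinstance(d, dt.datetime):
                raise DiaryError(f"index entry {d!r} is not a datetime.date")
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise DiaryError("entry dates must be strictly increasing")
        vals = data.to_numpy()
        ok = np.isnan(vals) | (vals == 0.0) | (vals == 1.0)
        if not ok.all():
            i, j = np.argwhere(~ok)[0]
            raise DiaryError(
                f"value {vals[i, j]!r} for {data.columns[j]!r} on {idx[i]} is not 0, 1 or missing"
            )
        self.data = data

        spans = sorted(self.phases, key=lambda s: s.start)
        for a, b in zip(spans, spans[1:]):
            if b.start <= a.end:
                raise DiaryError(f"phase spans overlap: {a.label} [{a.start}..{a.end}] and {b.label} [{b.start}..{b.end}]")

    # ------------------------------------------------------------------
    @classmethod
    def from_entries(
        cls,
        subject_id: str,
        variables: Sequence[VariableDef],
        entries: Iterable[DayRecord],
        phases: Sequence[PhaseSpan] = (),
    ) -> "Diary":
        entries = sorted(entries, key=lambda e: e.date)
        names = [v.name for v in variables]
        dates, rows = [], []
        for e in entries:
            if dates and e.date == dates[-1]:
                raise DiaryError(f"duplicate entry date {e.date}")
            extra = set(e.values) - set(names)
            if extra:
                raise DiaryError(f"entry {e.date} has values for undeclared variables {sorted(extra)}")
            dates.append(e.date)
            rows.append([np.nan if e.values.get(n) is None else float(e.values[n]) for n in names])
        data = pd.DataFrame(rows, index=dates, columns=names, dtype=float)
        return cls(subject_id, variables, data, phases)

    # ------------------------------------------------------------------
    @property
    def entries(self) -> list[DayRecord]:
        out = []
        for date, row in zip(self.data.index, self.data.to_numpy()):
            vals = {
                n: (None if np.isnan(v) else int(v))
                for n, v in zip(self.data.columns, row)
            }
            out.append(DayRecord(date, vals))
        return out

    @property
    def dates(self) -> list[dt.date]:
        return list(self.data.index)

    @property
    def outcomes(self) -> list[str]:
        return [v.name for v in self.variables if v.role == "outcome"]

    @property
    def factors(self) -> list[str]:
        return [v.name for v in self.variables if v.role == "factor"]

    def n_entries(self) -> int:
        return len(self.data)

    def role_of(self, name: str) -> str:
        for v in self.variables:
            if v.name == name:
                return v.role
        raise DiaryError(f"unknown variable {name!r}")

    def phase_of(self, date: dt.date) -> str:
        """Phase label governing ``date``; baseline when no span covers it."""
        for s in self.phases:
            if date in s:
                return s.label
        return BASELINE

    def has_phase(self, label: str) -> bool:
        return any(s.label == label for s in self.phases)

    # ------------------------------------------------------------------
    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Diary):
            return NotImplemented
        if (
            self.subject_id != other.subject_id
            or self.variables != other.variables
            or self.phases != other.phases
            or list(self.data.index) != list(other.data.index)
        ):
            return False
        a, b = self.data.to_numpy(), other.data.to_numpy()
        return bool(((a == b) | (np.isnan(a) & np.isnan(b))).all())

    def __repr__(self) -> str:
        return (
            f"Diary(subject_id={self.subject_id!r}, {len(self.data)} entries, "
            f"{len(self.outcomes)} outcome(s), {len(self.factors)} factor(s), "
            f"{len(self.phases)} phase span(s))"
        )


# ----------------------------------------------------------------------
# CSV I/O


def _parse_date(text: str, where: str) -> dt.date:
    try:
        return dt.date.fromisoformat(text)
    except ValueError as exc:
        raise DiaryError(f"{where}: invalid ISO date {text!r}") from exc


def read_diary(path: str | Path, roles: Mapping[str, str] | None = None) -> Diary:
    """Read a diary CSV (format in the module docstring).

    ``roles`` optionally maps variable name -> role and overrides both the
    ``#role`` directive and the first-column-is-outcome default.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        rows = list(csv.reader(fh))

    directives: list[list[str]] = []
    header: list[str] | None = None
    body: list[tuple[int, list[str]]] = []
    for lineno, row in enumerate(rows, start=1):
        if not row or all(c == "" for c in row):
            continue
        if row[0].startswith("#"):
            if header is not None:
                raise DiaryError(f"line {lineno}: directive after header")
            directives.append(row)
        elif header is None:
            header = row
        else:
            body.append((lineno, row))
    if header is None:
        raise DiaryError(f"{path}: no header row found")
    if header[0] != "date":
        raise DiaryError(f"{path}: first header column must be 'date', got {header[0]!r}")
    has_phase_col = len(header) > 1 and header[1] == "phase"
    var_names = header[2:] if has_phase_col else header[1:]
    if not var_names:
        raise DiaryError(f"{path}: no variable columns")

    subject_id = path.stem
    role_map: dict[str, str] = {}
    phase_spans: list[PhaseSpan] = []
    for d in directives:
        key = d[0]
        if key == "#subject":
            subject_id = d[1] if len(d) > 1 else ""
        elif key == "#role":
            cells = d[1:]
            # cells align with header columns after 'date'
            offset = 1 if has_phase_col else 0
            if len(cells) - offset != len(var_names):
                raise DiaryError("#role directive does not align with header columns")
            role_map = dict(zip(var_names, cells[offset:]))
        elif key == "#phase":
            if len(d) < 4:
                raise DiaryError("#phase directive needs label,start,end")
            label = d[1]
            if label not in PHASE_LABELS:
                raise DiaryError(f"unknown phase label {label!r} in #phase directive")
            phase_spans.append(
                PhaseSpan(label, _parse_date(d[2], "#phase start"), _parse_date(d[3], "#phase end"), d[4] if len(d) > 4 else "")
            )
        else:
            raise DiaryError(f"unknown directive {key!r}")

    if roles is not None:
        role_map = dict(roles)
    if not role_map:
        role_map = {n: ("outcome" if i == 0 else "factor") for i, n in enumerate(var_names)}
    missing = [n for n in var_names if n not in role_map]
    if missing:
        raise DiaryError(f"no role declared for variable(s) {missing}")
    variables = [VariableDef(n, role_map[n]) for n in var_names]

    seen: dict[dt.date, int] = {}
    dates: list[dt.date] = []
    vals: list[list[float]] = []
    row_labels: list[tuple[dt.date, str]] = []
    for lineno, row in body:
        row = row + [""] * (len(header) - len(row))
        if len(row) > len(header):
            raise DiaryError(f"line {lineno}: more cells than header columns")
        date = _parse_date(row[0], f"line {lineno}")
        if date in seen:
            raise DiaryError(f"duplicate date {date} (lines {seen[date]} and {lineno})")
        seen[date] = lineno
        if has_phase_col:
            label = row[1]
            if label not in ("",) + PHASE_LABELS:
                raise DiaryError(f"line {lineno}: unknown phase label {label!r}")
            if label:
                row_labels.append((date, label))
        cells = row[2:] if has_phase_col else row[1:]
        parsed = []
        for name, cell in zip(var_names, cells):
            if cell == "":
                parsed.append(np.nan)
            elif cell in ("0", "1"):
                parsed.append(float(cell))
            else:
                raise DiaryError(f"line {lineno}, column {name!r}: value {cell!r} is not 0, 1 or blank")
        dates.append(date)
        vals.append(parsed)

    order = np.argsort(dates, kind="stable")
    dates = [dates[i] for i in order]
    vals = [vals[i] for i in order]
    data = pd.DataFrame(vals, index=dates, columns=var_names, dtype=float)

    if not phase_spans and row_labels:
        phase_spans = _spans_from_row_labels(sorted(row_labels))
    diary = Diary(subject_id, variables, data, phase_spans)
    if phase_spans:
        for date, label in row_labels:
            if diary.phase_of(date) != label:
                raise DiaryError(f"phase column says {label!r} on {date} but declared spans say {diary.phase_of(date)!r}")
    return diary


def _spans_from_row_labels(row_labels: list[tuple[dt.date, str]]) -> list[PhaseSpan]:
    """Collapse per-row phase labels into maximal runs of a single label."""
    spans: list[PhaseSpan] = []
    start, prev_date, prev_label = None, None, None
    for date, label in row_labels:
        if label != prev_label:
            if prev_label is not None:
                spans.append(PhaseSpan(prev_label, start, prev_date))
            start, prev_label = date, label
        prev_date = date
    spans.append(PhaseSpan(prev_label, start, prev_date))
    return spans


def write_diary(diary: Diary, path: str | Path) -> None:
    """Serialize ``diary`` so that :func:`read_diary` reproduces it exactly."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        fh.write(diary_to_csv(diary))


def diary_to_csv(diary: Diary) -> str:
    buf = io.StringIO()
    w = csv.writer(buf, lineterminator="\n")
    w.writerow(["#subject", diary.subject_id])
    w.writerow(["#role", ""] + [v.role for v in diary.variables])
    for s in diary.phases:
        w.writerow(["#phase", s.label, s.start.isoformat(), s.end.isoformat(), s.note])
    w.writerow(["date", "phase"] + [v.name for v in diary.variables])
    for date, row in zip(diary.data.index, diary.data.to_numpy()):
        label = ""
        for s in diary.phases:
            if date in s:
                label = s.label
                break
        cells = ["" if np.isnan(v) else str(int(v)) for v in row]
        w.writerow([date.isoformat(), label] + cells)
    return buf.getvalue()


def slice_phase(diary: Diary, label: str) -> Diary:
    """Sub-diary of the entries governed by ``label`` (baseline-by-default rule)."""
    if label not in PHASE_LABELS:
        raise DiaryError(f"unknown phase label {label!r}; expected one of {PHASE_LABELS}")
    mask = [diary.phase_of(d) == label for d in diary.data.index]
    spans = [s for s in diary.phases if s.label == label]
    return Diary(diary.subject_id, diary.variables, diary.data.loc[mask], spans)
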