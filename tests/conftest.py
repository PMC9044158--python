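"""Shared fixtures and random-diary generators."""

from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from nof1diary import Diary, PhaseSpan, VariableDef


def make_random_diary(rng: np.random.Generator) -> Diary:
    """A structurally varied random diary: gaps, missing cells, 0-2 phases."""
    n_days = int(rng.integers(0, 60))
    start = dt.date(2021, 1, 1) + dt.timedelta(days=int(rng.integers(0, 300)))
    span = max(n_days, 1) + int(rng.integers(0, 20))
    offsets = sorted(rng.choice(span, size=n_days, replace=False)) if n_days else []
    dates = [start + dt.timedelta(days=int(o)) for o in offsets]

    n_factors = int(rng.integers(0, 3))
    variables = [VariableDef("sym", "outcome")] + [
        VariableDef(f"f{i}", "factor") for i in range(n_factors)
    ]
    vals = rng.choice([0.0, 1.0, np.nan], size=(n_days, 1 + n_factors), p=[0.4, 0.4, 0.2])
    data = pd.DataFrame(vals, index=dates, columns=[v.name for v in variables])

    phases = []
    if n_days and rng.random() < 0.6:
        cut = int(rng.integers(0, n_days))
        if cut > 0:
            phases.append(PhaseSpan("baseline", dates[0], dates[cut - 1]))
        if cut < n_days:
            phases.append(
                PhaseSpan("intervention", dates[cut], dates[-1], note="note, with comma")
            )
    return Diary(f"subj{rng.integers(1000)}", variables, data, phases)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


@pytest.fixture
def simple_csv(tmp_path):
    """Plain headered CSV: no directives, roles by first-column default."""
    p = tmp_path / "diary.csv"
    p.write_text(
        "date,phase,migraine,caffeine\n"
        "2020-01-01,baseline,1,1\n"
        "2020-01-02,baseline,0,1\n"
        "2020-01-03,baseline,1,0\n"
        "2020-01-04,baseline,0,0\n"
        "2020-01-05,baseline,1,1\n"
    )
    return p
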