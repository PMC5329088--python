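"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

from datetime import date, timedelta

import pandas as pd
import pytest

from adtrends.config import StudyConfig


@pytest.fixture(scope="session")
def study() -> StudyConfig:
    return StudyConfig()


def make_patients(rows) -> pd.DataFrame:
    """Build a patient table from (id, sex, birth, reg_start, reg_end) tuples.

    ``reg_end=None`` means still registered at the data end.
    """
    out = pd.DataFrame(
        rows, columns=["patient_id", "sex", "birth_date", "reg_start", "reg_end"]
    )
    out["acceptable"] = True
    out["depression_flag"] = False
    return out


def make_therapy(rows) -> pd.DataFrame:
    """Build a therapy table from (id, issue_date, product, dose, qty, units/day)."""
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "issue_date",
            "product_name",
            "daily_dose_mg",
            "quantity",
            "units_per_day",
        ],
    )


def brute_force_episodes(issue_dates, durations, config: StudyConfig):
    """Transitive-closure interval merge: the independent episode oracle.

    Two scripts belong to the same episode whenever the later one is issued
    before the earlier one's expected end plus the gap threshold; membership
    closes transitively.  O(n^2) union-find over all script pairs, using
    pandas date offsets for the calendar-month gap (an implementation of the
    gap rule independent of the package's own).
    """
    n = len(issue_dates)
    starts = [pd.Timestamp(d) for d in issue_dates]
    ends = [s + pd.Timedelta(days=int(du)) for s, du in zip(starts, durations)]
    if config.gap_days is not None:
        cutoffs = [e + pd.Timedelta(days=config.gap_days) for e in ends]
    else:
        cutoffs = [e + pd.DateOffset(months=config.gap_months) for e in ends]

    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            early, late = (i, j) if (starts[i], i) <= (starts[j], j) else (j, i)
            if starts[late] < cutoffs[early]:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[ri] = rj

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    episodes = []
    for members in groups.values():
        start = min(starts[m] for m in members)
        end = max(ends[m] for m in members)
        episodes.append((start.date(), end.date(), len(members)))
    return sorted(episodes)


def random_rx_stream(rng, max_scripts=8, span_days=900):
    """A small random prescription stream (dates + durations) for oracle tests."""
    n = int(rng.integers(1, max_scripts + 1))
    base = date(1995, 1, 1) + timedelta(days=int(rng.integers(0, 3650)))
    dates = sorted(
        base + timedelta(days=int(rng.integers(0, span_days))) for _ in range(n)
    )
    durs = [int(rng.integers(1, 120)) for _ in range(n)]
    return dates, durs
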