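"""Treatment-episode construction from prescription streams.

The intended duration of each prescription is estimated from the dosing
instruction and the quantity prescribed (``quantity / units_per_day``,
rounded half-up, floored at one day).  Where no instruction was recorded, the
median duration-per-script for the product is used, falling back to the
global median across products.

Consecutive prescriptions belong to the same treatment episode when the gap
between the expected end of one prescription and the issue of the next is
less than the stitching threshold (4 calendar months by default; a fixed
day-count gap is available via ``StudyConfig.gap_days``).  Prescriptions need
not share a product or drug class.  Overlapping scripts extend a running
expected end (no stockpiling is assumed), so an episode's duration is the
calendar span from its first issue to its final expected end.

Episode durations fall into six categories (<=30, 31-60, 61-180, 181-365,
366-730, 731+ days); "long-term use" means a duration greater than one year.

A patient's first-ever episode is *incident* when the patient also has the
required drug-free registration lookback (3 years by default) at its start;
any later episode of the same patient is never incident.
"""

from __future__ import annotations

import math
from datetime import date, timedelta
from typing import Mapping

import numpy as np
import pandas as pd

from ._dates import add_months, to_date
from .config import StudyConfig
from .cohort import has_lookback

__all__ = [
    "compute_product_medians",
    "prescription_duration",
    "stitch_episodes",
    "build_episodes",
    "classify_duration",
    "duration_labels",
    "flag_incident",
]

THERAPY_COLUMNS = [
    "patient_id",
    "issue_date",
    "product_name",
    "daily_dose_mg",
    "quantity",
    "units_per_day",
]


def _round_days(x: float) -> int:
    """Round half-up to whole days, never below one."""
    return max(1, int(math.floor(float(x) + 0.5)))


def compute_product_medians(prescriptions: pd.DataFrame) -> dict[str, float]:
    """Median duration-per-script (days) per product, over instruction-complete scripts.

    Products with no instruction-complete script are absent from the map.
    """
    if prescriptions.empty:
        return {}
    rx = prescriptions
    ok = rx["units_per_day"].notna() & (pd.to_numeric(rx["units_per_day"], errors="coerce") > 0)
    if not ok.any():
        return {}
    sub = rx.loc[ok]
    days = sub["quantity"].astype(float) / sub["units_per_day"].astype(float)
    med = days.groupby(sub["product_name"].astype(str).str.strip().str.lower()).median()
    return med.to_dict()


def global_median(medians: Mapping[str, float]) -> float | None:
    if not medians:
        return None
    return float(np.median(list(medians.values())))


def prescription_duration(rx, medians: Mapping[str, float]) -> int:
    """Estimated intended duration of one prescription, in whole days (>=1).

    Fallback chain: instruction arithmetic, then the product median, then the
    global median across products.
    """
    qty = float(rx["quantity"])
    if qty <= 0:
        raise ValueError("quantity must be positive")
    upd = rx.get("units_per_day") if hasattr(rx, "get") else rx["units_per_day"]
    if upd is not None and not pd.isna(upd) and float(upd) > 0:
        return _round_days(qty / float(upd))
    key = str(rx["product_name"]).strip().lower()
    if key in medians:
        return _round_days(medians[key])
    g = global_median(medians)
    if g is None:
        raise ValueError(
            f"cannot estimate duration for {rx['product_name']!r}: no instruction-complete "
            "prescriptions anywhere in the data"
        )
    return _round_days(g)


def _gap_end(expected_end: date, config: StudyConfig) -> date:
    """First issue date that would open a new episode after ``expected_end``."""
    if config.gap_days is not None:
        return expected_end + timedelta(days=config.gap_days)
    return add_months(expected_end, config.gap_months)


def stitch_episodes(
    issue_dates: list[date], durations: list[int], config: StudyConfig
) -> list[tuple[date, date, int]]:
    """Greedy left-to-right merge of one patient's scripts into episodes.

    Returns ``(start, expected_end, n_scripts)`` per episode.  A new episode
    opens when a script is issued on or after the running expected end plus
    the gap threshold; otherwise the script joins the current episode and the
    expected end becomes ``max(previous end, issue + duration)``.
    """
    order = sorted(range(len(issue_dates)), key=lambda i: issue_dates[i])
    episodes: list[tuple[date, date, int]] = []
    start = end = None
    n = 0
    for i in order:
        d, dur = issue_dates[i], int(durations[i])
        script_end = d + timedelta(days=dur)
        if start is None:
            start, end, n = d, script_end, 1
        elif d >= _gap_end(end, config):
            episodes.append((start, end, n))
            start, end, n = d, script_end, 1
        else:
            end = max(end, script_end)
            n += 1
    if start is not None:
        episodes.append((start, end, n))
    return episodes


def build_episodes(
    therapy: pd.DataFrame,
    config: StudyConfig,
    medians: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Stitch a classified therapy table into one row per treatment episode.

    ``therapy`` needs the standard columns plus ``drug_class`` (see
    :func:`adtrends.drugs.classify_table`).  Durations beyond the end of the
    data window are censored there.  Output columns: ``patient_id,
    start_date, expected_end_date, duration_days, n_prescriptions,
    classes_present, first_class, start_year``.
    """
    cols = [
        "patient_id",
        "start_date",
        "expected_end_date",
        "duration_days",
        "n_prescriptions",
        "classes_present",
        "first_class",
        "start_year",
    ]
    if therapy.empty:
        return pd.DataFrame(columns=cols)
    if medians is None:
        medians = compute_product_medians(therapy)

    rx = therapy.sort_values(["patient_id", "issue_date"], kind="mergesort")
    dates = [to_date(d) for d in rx["issue_date"]]
    durs = [prescription_duration(row, medians) for _, row in rx.iterrows()]
    classes = rx["drug_class"].astype(str).tolist() if "drug_class" in rx else [""] * len(rx)
    pids = rx["patient_id"].tolist()
    data_end = date(config.study_end_year, 12, 31) + timedelta(days=1)

    rows = []
    i = 0
    while i < len(pids):
        j = i
        while j < len(pids) and pids[j] == pids[i]:
            j += 1
        # per-patient greedy stitch, tracking member scripts for class unions
        start = end = None
        members: list[int] = []

        def _close():
            span_end = min(end, data_end)
            dur = max(1, (span_end - start).days)
            present = sorted({classes[m] for m in members if classes[m]})
            rows.append(
                (
                    pids[i],
                    start,
                    span_end,
                    dur,
                    len(members),
                    "+".join(present),
                    classes[members[0]] if members else "",
                    start.year,
                )
            )

        for k in range(i, j):
            d = dates[k]
            script_end = d + timedelta(days=durs[k])
            if start is None:
                start, end, members = d, script_end, [k]
            elif d >= _gap_end(end, config):
                _close()
                start, end, members = d, script_end, [k]
            else:
                end = max(end, script_end)
                members.append(k)
        if start is not None:
            _close()
        i = j
    return pd.DataFrame(rows, columns=cols)


def duration_labels(config: StudyConfig) -> list[str]:
    """Ordered category labels implied by the duration cut points."""
    bins = config.duration_bins_days
    labels = [f"<={bins[0]}"]
    labels += [f"{a + 1}-{b}" for a, b in zip(bins, bins[1:])]
    labels.append(f"{bins[-1] + 1}+")
    return labels


def classify_duration(duration_days: int, config: StudyConfig) -> str:
    """Assign a duration category; boundaries are inclusive on the upper end."""
    if duration_days < 1:
        raise ValueError("duration_days must be >= 1")
    labels = duration_labels(config)
    for cut, label in zip(config.duration_bins_days, labels):
        if duration_days <= cut:
            return label
    return labels[-1]


def is_long_term(duration_days: int) -> bool:
    """Long-term use: a treatment episode lasting more than one year."""
    return duration_days > 365


def flag_incident(
    episodes: pd.DataFrame, patients: pd.DataFrame, config: StudyConfig
) -> pd.DataFrame:
    """Set the ``incident`` flag on an episode table.

    An episode is incident iff it is the patient's first-ever episode in the
    extracted data *and* the patient had been registered for the full
    lookback period at its start.  First-ever episodes without the lookback
    are not incident (and therefore never enter incidence numerators).
    """
    out = episodes.copy()
    if out.empty:
        out["incident"] = pd.Series(dtype=bool)
        return out
    out = out.sort_values(["patient_id", "start_date"], kind="mergesort", ignore_index=True)
    first = ~out["patient_id"].duplicated()
    reg = patients.set_index("patient_id")["reg_start"]
    reg_start = out["patient_id"].map(reg)
    if reg_start.isna().any():
        missing = out.loc[reg_start.isna(), "patient_id"].unique()
        raise ValueError(f"episodes reference unknown patient(s): {list(missing)[:5]}")
    ok = [
        has_lookback({"reg_start": rs}, sd, config)
        for rs, sd in zip(reg_start, out["start_date"])
    ]
    out["incident"] = first & pd.Series(ok, index=out.index)
    return out
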