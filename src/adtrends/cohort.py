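"""Cohort eligibility and person-years-at-risk denominators.

A patient contributes person-time to a calendar year for the fraction of that
year during which they are simultaneously (a) registered with the practice,
(b) past the minimum age (14 by default), and (c) past the required
registration history (3 years by default).  All intervals are half-open
``[start, end)`` at day resolution, so a patient registered for exactly three
months of a year and then leaving contributes 0.25 person-years to that
year's denominator.  Leap years use their actual day count.

Age changes mid-year split person-time at the birthday, both for the minimum
age filter and for age-band stratification, so each day of person-time is
assigned to the band containing the patient's age on that day.
"""

from __future__ import annotations

from datetime import date
from typing import Mapping

import numpy as np
import pandas as pd

from ._dates import add_years, days_in_year, to_date, year_start_ordinal
from .config import StudyConfig

__all__ = [
    "has_lookback",
    "person_time_in_year",
    "build_person_time_table",
    "age_band_labels",
    "eligibility_bounds",
]

STRATA_SPECS = ("none", "sex", "age_band")

_FAR_FUTURE = date(9999, 1, 1).toordinal()


def has_lookback(patient, when, config: StudyConfig) -> bool:
    """True iff the patient has the required registration history at ``when``.

    Uses calendar-anniversary arithmetic: a prescription in July 2000 under a
    3-year lookback requires registration since at least July 1997 (the
    boundary date itself qualifies).
    """
    reg_start = to_date(patient["reg_start"] if hasattr(patient, "__getitem__") else patient)
    return reg_start <= add_years(to_date(when), -config.lookback_years)


def _patient_window(patient, config: StudyConfig) -> tuple[int, int]:
    """Eligible interval [start, end) for one patient, as date ordinals."""
    reg_start = to_date(patient["reg_start"])
    birth = to_date(patient["birth_date"])
    start = max(
        add_years(reg_start, config.lookback_years)
        if config.require_lookback_for_person_time
        else reg_start,
        add_years(birth, config.min_age_years),
        to_date(config.extraction_start),
    ).toordinal()
    reg_end = patient.get("reg_end") if hasattr(patient, "get") else patient["reg_end"]
    end = _FAR_FUTURE if pd.isna(reg_end) else to_date(reg_end).toordinal()
    return start, end


def person_time_in_year(patient, year: int, config: StudyConfig) -> float:
    """Fraction of calendar ``year`` the patient contributes to the denominator."""
    if not (config.study_start_year <= year <= config.study_end_year):
        raise ValueError(f"year {year} outside the study window")
    if hasattr(patient, "get") and patient.get("acceptable") is False:
        return 0.0
    start, end = _patient_window(patient, config)
    y0 = year_start_ordinal(year)
    y1 = year_start_ordinal(year + 1)
    overlap = min(end, y1) - max(start, y0)
    return max(overlap, 0) / days_in_year(year)


def age_band_labels(config: StudyConfig) -> list[str]:
    edges = config.age_band_edges
    labels = [f"<{edges[0]}"]
    labels += [f"{a}-{b - 1}" for a, b in zip(edges, edges[1:])]
    labels.append(f"{edges[-1]}+")
    return labels


def eligibility_bounds(
    patients: pd.DataFrame,
    config: StudyConfig,
    censor_dates: Mapping | pd.Series | None = None,
) -> pd.DataFrame:
    """Per-patient eligible interval [start, end) as ordinals.

    ``censor_dates`` (patient_id -> date) additionally truncates each
    patient's interval, e.g. at the first-ever antidepressant prescription to
    obtain drug-naive (at-risk) person-time.  Unacceptable records get an
    empty interval.
    """
    rows = []
    for _, p in patients.iterrows():
        start, end = _patient_window(p, config)
        if not bool(p.get("acceptable", True)):
            end = start  # empty interval
        rows.append((p["patient_id"], start, end))
    out = pd.DataFrame(rows, columns=["patient_id", "elig_start", "elig_end"])
    if censor_dates is not None:
        cs = pd.Series(dict(censor_dates)) if not isinstance(censor_dates, pd.Series) else censor_dates
        cut = out["patient_id"].map(cs)
        mask = cut.notna()
        ords = cut[mask].map(lambda d: to_date(d).toordinal())
        out.loc[mask, "elig_end"] = np.minimum(out.loc[mask, "elig_end"], ords)
    return out


def build_person_time_table(
    patients: pd.DataFrame,
    config: StudyConfig,
    strata_spec: str = "none",
    censor_dates: Mapping | pd.Series | None = None,
) -> pd.DataFrame:
    """Person-years at risk per (calendar year, stratum).

    ``strata_spec`` is one of ``"none"`` (single ``all`` stratum), ``"sex"``
    (F/M) or ``"age_band"``.  Returns a tidy frame with columns
    ``year, stratum, person_years`` covering every study year (zeros kept),
    sex- and age-stratified tables partition the unstratified person-time
    exactly.
    """
    if strata_spec not in STRATA_SPECS:
        raise ValueError(f"unknown strata_spec {strata_spec!r}; expected one of {STRATA_SPECS}")
    years = list(config.study_years)
    if patients.empty:
        return pd.DataFrame(columns=["year", "stratum", "person_years"])

    bounds = eligibility_bounds(patients, config, censor_dates=censor_dates)
    start = bounds["elig_start"].to_numpy(dtype=np.int64)
    end = bounds["elig_end"].to_numpy(dtype=np.int64)

    if strata_spec == "age_band":
        labels = age_band_labels(config)
        births = [to_date(b) for b in patients["birth_date"]]
        edge_ords = np.array(
            [[add_years(b, int(a)).toordinal() for a in config.age_band_edges] for b in births],
            dtype=np.int64,
        )
        # band k spans [edge_{k-1}, edge_k); open at both extremes
        lo = np.concatenate([np.zeros((len(births), 1), dtype=np.int64), edge_ords], axis=1)
        hi = np.concatenate(
            [edge_ords, np.full((len(births), 1), _FAR_FUTURE, dtype=np.int64)], axis=1
        )
        segments = [
            (labels[k], np.maximum(start, lo[:, k]), np.minimum(end, hi[:, k]))
            for k in range(len(labels))
        ]
    elif strata_spec == "sex":
        sexes = patients["sex"].astype(str).to_numpy()
        segments = [
            (s, np.where(sexes == s, start, 0), np.where(sexes == s, end, 0))
            for s in ("F", "M")
        ]
    else:
        segments = [("all", start, end)]

    rows = []
    for label, seg_start, seg_end in segments:
        for year in years:
            y0, y1 = year_start_ordinal(year), year_start_ordinal(year + 1)
            overlap = np.minimum(seg_end, y1) - np.maximum(seg_start, y0)
            py = np.clip(overlap, 0, None).sum() / days_in_year(year)
            rows.append((year, label, float(py)))
    out = pd.DataFrame(rows, columns=["year", "stratum", "person_years"])
    return out.sort_values(["year", "stratum"], ignore_index=True)
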