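"""Annual prevalence and incidence rates per 1000 person-years.

*Period prevalence* counts, for each calendar year, the distinct eligible
patients with at least one antidepressant prescription issued in that year
(per drug class when stratified: a patient may count in several classes but
only once per class per year).  *Incidence* counts incident treatment
episodes starting in the year (at most one per patient, by construction of
the incident flag).  Both use person-years at risk as the denominator and
report ``1000 * numerator / person_years``.

Also here: the female:male rate-ratio series with a chi-square test for
linear trend (Cochran-Armitage with calendar-year scores), the
duration-of-treatment trend tables, and the two sensitivity-analysis filters
(low-dose amitriptyline exclusion and the depression-flag subgroup).
"""

from __future__ import annotations

import warnings
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from ._dates import add_years, to_date
from .config import StudyConfig
from .cohort import age_band_labels, eligibility_bounds
from .drugs import flag_low_dose_table
from .episodes import classify_duration, duration_labels

__all__ = [
    "period_prevalence",
    "incidence",
    "sex_ratio_series",
    "cochran_armitage_trend",
    "duration_trend",
    "apply_sensitivity",
]

SENSITIVITY_MODES = ("exclude_low_dose_ami", "depression_subgroup")


def _age_band(birth, when, config: StudyConfig) -> str:
    labels = age_band_labels(config)
    b = to_date(birth)
    w = to_date(when)
    for edge, label in zip(config.age_band_edges, labels):
        if w < add_years(b, int(edge)):
            return label
    return labels[-1]


def _event_mask(dates: pd.Series, pids: pd.Series, patients: pd.DataFrame, config: StudyConfig):
    """Events are countable only inside their patient's eligible window."""
    bounds = eligibility_bounds(patients, config).set_index("patient_id")
    lo = pids.map(bounds["elig_start"])
    hi = pids.map(bounds["elig_end"])
    if lo.isna().any():
        unknown = pids[lo.isna()].unique()
        raise ValueError(f"events reference unknown patient(s): {list(unknown)[:5]}")
    ords = dates.map(lambda d: to_date(d).toordinal())
    return (ords >= lo) & (ords < hi)


def _assemble(numerators: pd.DataFrame, person_time: pd.DataFrame) -> pd.DataFrame:
    """Join numerators onto the person-time grid and compute rates."""
    out = person_time.merge(numerators, on=["year", "stratum"], how="outer")
    out["numerator"] = out["numerator"].fillna(0).astype(int)
    out["person_years"] = out["person_years"].fillna(0.0)
    bad = (out["person_years"] <= 0) & (out["numerator"] > 0)
    if bad.any():
        rows = out.loc[bad, ["year", "stratum"]].to_records(index=False).tolist()
        raise ValueError(f"nonzero numerator with zero person-years at {rows[:5]}")
    with np.errstate(divide="ignore", invalid="ignore"):
        out["rate_per_1000py"] = np.where(
            out["person_years"] > 0, 1000.0 * out["numerator"] / out["person_years"], 0.0
        )
    cols = ["year", "stratum", "numerator", "person_years", "rate_per_1000py"]
    return out[cols].sort_values(["year", "stratum"], ignore_index=True)


def _strata_of_events(kind, dates, pids, classes, patients, config) -> pd.Series:
    if kind == "none":
        return pd.Series("all", index=dates.index)
    if kind == "sex":
        return pids.map(patients.set_index("patient_id")["sex"].astype(str))
    if kind == "age_band":
        births = pids.map(patients.set_index("patient_id")["birth_date"])
        return pd.Series(
            [_age_band(b, d, config) for b, d in zip(births, dates)], index=dates.index
        )
    if kind == "drug_class":
        return classes.astype(str)
    raise ValueError(f"unknown strata_spec {kind!r}")


def period_prevalence(
    therapy: pd.DataFrame,
    person_time: pd.DataFrame,
    patients: pd.DataFrame,
    config: StudyConfig,
    strata_spec: str = "none",
) -> pd.DataFrame:
    """Patients with >=1 prescription in the year, per 1000 person-years.

    ``therapy`` must carry a ``drug_class`` column when
    ``strata_spec="drug_class"`` (denominators are then the unstratified
    person-time, i.e. crude class-specific rates over the whole cohort).
    """
    rx = therapy
    if rx.empty:
        return _assemble(pd.DataFrame(columns=["year", "stratum", "numerator"]), person_time)
    dates = rx["issue_date"]
    pids = rx["patient_id"]
    ok = _event_mask(dates, pids, patients, config)
    years = dates.map(lambda d: to_date(d).year)
    ok &= years.between(config.study_start_year, config.study_end_year)
    sub = rx.loc[ok]
    strat = _strata_of_events(
        strata_spec,
        sub["issue_date"],
        sub["patient_id"],
        sub.get("drug_class", pd.Series(index=sub.index, dtype=object)),
        patients,
        config,
    )
    grp = pd.DataFrame(
        {"year": years.loc[ok], "stratum": strat, "patient_id": sub["patient_id"]}
    )
    num = (
        grp.drop_duplicates()
        .groupby(["year", "stratum"], as_index=False)["patient_id"]
        .nunique()
        .rename(columns={"patient_id": "numerator"})
    )
    if strata_spec == "drug_class":
        # replicate the overall denominator for each class
        classes = sorted(grp["stratum"].dropna().unique())
        pt = (
            pd.concat([person_time.assign(stratum=c) for c in classes], ignore_index=True)
            if classes
            else person_time.iloc[0:0]
        )
    else:
        pt = person_time
    return _assemble(num, pt)


def incidence(
    episodes: pd.DataFrame,
    person_time: pd.DataFrame,
    patients: pd.DataFrame,
    config: StudyConfig,
    strata_spec: str = "none",
) -> pd.DataFrame:
    """Incident treatment-episode starts per 1000 person-years.

    ``episodes`` must carry the ``incident`` flag (see
    :func:`adtrends.episodes.flag_incident`).  The caller chooses the
    denominator: pass the standard person-time table for rates comparable to
    period prevalence, or a table censored at the first-ever prescription
    (``build_person_time_table(..., censor_dates=...)``) for drug-naive
    person-time, which is the unbiased estimator of the starting hazard.
    """
    if episodes.empty:
        return _assemble(pd.DataFrame(columns=["year", "stratum", "numerator"]), person_time)
    inc = episodes.loc[episodes["incident"].astype(bool)]
    if inc.empty:
        return _assemble(pd.DataFrame(columns=["year", "stratum", "numerator"]), person_time)
    dates = inc["start_date"]
    pids = inc["patient_id"]
    ok = _event_mask(dates, pids, patients, config)
    years = dates.map(lambda d: to_date(d).year)
    ok &= years.between(config.study_start_year, config.study_end_year)
    sub = inc.loc[ok]
    strat = _strata_of_events(
        strata_spec,
        sub["start_date"],
        sub["patient_id"],
        sub.get("first_class", pd.Series(index=sub.index, dtype=object)),
        patients,
        config,
    )
    num = (
        pd.DataFrame({"year": years.loc[ok], "stratum": strat})
        .groupby(["year", "stratum"], as_index=False)
        .size()
        .rename(columns={"size": "numerator"})
    )
    if strata_spec == "drug_class":
        classes = sorted(num["stratum"].dropna().unique())
        pt = (
            pd.concat([person_time.assign(stratum=c) for c in classes], ignore_index=True)
            if classes
            else person_time.iloc[0:0]
        )
    else:
        pt = person_time
    return _assemble(num, pt)


def cochran_armitage_trend(events_a: np.ndarray, events_b: np.ndarray, scores: np.ndarray) -> dict:
    """Chi-square test for linear trend in the proportion a/(a+b) over ordered groups.

    Textbook Cochran-Armitage statistic with arbitrary scores (here calendar
    years); returns ``{"chi2", "pvalue", "z"}`` with 1 degree of freedom.
    """
    a = np.asarray(events_a, dtype=float)
    n = a + np.asarray(events_b, dtype=float)
    x = np.asarray(scores, dtype=float)
    keep = n > 0
    a, n, x = a[keep], n[keep], x[keep]
    big_n = n.sum()
    pbar = a.sum() / big_n
    t = float((x * a).sum() - pbar * (x * n).sum())
    var = pbar * (1 - pbar) * float((n * x**2).sum() - (n * x).sum() ** 2 / big_n)
    if var <= 0:
        return {"chi2": 0.0, "pvalue": 1.0, "z": 0.0}
    chi2 = t * t / var
    return {"chi2": chi2, "pvalue": float(stats.chi2.sf(chi2, df=1)), "z": t / var**0.5}


def sex_ratio_series(rates_by_sex: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Female:male rate ratio per year plus a chi-square test of trend.

    ``rates_by_sex`` is a rate series with strata F and M.  Years where the
    male rate is zero get a missing ratio.  The trend test is
    Cochran-Armitage on the per-year (female, male) event counts with the
    year as the score.
    """
    wide = rates_by_sex.pivot(index="year", columns="stratum")
    rate = wide["rate_per_1000py"]
    num = wide["numerator"]
    missing = {"F", "M"} - set(rate.columns)
    if missing:
        raise ValueError(f"both sex strata required; missing {sorted(missing)}")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(rate["M"] > 0, rate["F"] / rate["M"], np.nan)
    out = pd.DataFrame({"year": rate.index, "fm_ratio": ratio}).reset_index(drop=True)
    test = cochran_armitage_trend(
        num["F"].to_numpy(), num["M"].to_numpy(), rate.index.to_numpy()
    )
    return out, test


def duration_trend(episodes: pd.DataFrame, config: StudyConfig) -> dict[str, pd.DataFrame]:
    """Duration-category proportions and median duration by start year.

    Restricted to incident episodes with ``start_year`` between the study
    start and ``duration_last_start_year`` (so every episode has at least two
    years of observable follow-up before the data end).  Start years with no
    incident episodes are omitted with a warning.
    """
    inc = episodes.loc[
        episodes["incident"].astype(bool)
        & episodes["start_year"].between(config.study_start_year, config.duration_last_start_year)
    ]
    labels = duration_labels(config)
    props, meds = [], []
    for year in range(config.study_start_year, config.duration_last_start_year + 1):
        sub = inc.loc[inc["start_year"] == year, "duration_days"]
        if sub.empty:
            warnings.warn(f"no incident episodes starting in {year}; year omitted")
            continue
        cats = sub.map(lambda d: classify_duration(int(d), config))
        counts = cats.value_counts()
        total = int(counts.sum())
        for label in labels:
            c = int(counts.get(label, 0))
            props.append((year, label, c, c / total))
        meds.append((year, total, float(sub.median())))
    return {
        "proportions": pd.DataFrame(
            props, columns=["start_year", "category", "n", "proportion"]
        ),
        "medians": pd.DataFrame(
            meds, columns=["start_year", "n", "median_duration_days"]
        ),
    }


def apply_sensitivity(
    therapy: pd.DataFrame,
    patients: pd.DataFrame,
    mode: str,
    config: StudyConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Filter inputs for a sensitivity analysis; downstream stages run unchanged.

    ``exclude_low_dose_ami`` removes amitriptyline prescriptions below
    75 mg/day (and, with ``low_dose_exclusion_level="patient"``, additionally
    drops patients *all* of whose prescriptions were flagged).
    ``depression_subgroup`` keeps only patients carrying the depression flag.
    """
    if mode not in SENSITIVITY_MODES:
        raise ValueError(f"unknown sensitivity mode {mode!r}; expected one of {SENSITIVITY_MODES}")
    config = config or StudyConfig()
    if mode == "depression_subgroup":
        keep = patients.loc[patients["depression_flag"].astype(bool)]
        ids = set(keep["patient_id"])
        return therapy.loc[therapy["patient_id"].isin(ids)].copy(), keep.copy()
    flagged = flag_low_dose_table(therapy) if not therapy.empty else pd.Series(dtype=bool)
    rx = therapy.loc[~flagged].copy() if not therapy.empty else therapy.copy()
    pats = patients
    if config.low_dose_exclusion_level == "patient" and not therapy.empty:
        all_flagged = flagged.groupby(therapy["patient_id"]).all()
        drop = set(all_flagged.index[all_flagged])
        pats = patients.loc[~patients["patient_id"].isin(drop)].copy()
        rx = rx.loc[~rx["patient_id"].isin(drop)].copy()
    return rx, pats.copy()
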