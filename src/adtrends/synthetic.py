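"""Synthetic primary-care prescribing data with known ground truth.

Generates a patient table and a therapy (prescription) table shaped like an
anonymised primary-care extract, together with the latent truth that
produced them, so that every downstream stage — episode stitching, incident
detection, person-time denominators, rate and trend estimation — can be
tested against known parameters without any restricted data access.

The generating process, per patient:

1. A registration interval inside the data window (a configurable fraction
   of patients are already registered when the window opens), with a
   constant exit hazard.
2. A first-ever treatment start drawn from a piecewise-constant calendar-year
   hazard (per 1000 person-years), modulated by a female:male ratio; later
   episodes use the same hazard scaled by ``restart_hazard_multiplier``.
3. Each episode draws a drug class from the per-year class mix, a product
   and daily dose from within-class frequency tables, and a log-normal
   intended duration whose median depends on the start year.  Repeat
   prescriptions are issued every ``refill_interval_days``, the last one
   sized to the remaining days; a configurable fraction of scripts lose
   their dosing instruction.
4. Consecutive latent episodes are separated by strictly more than the
   4-month stitching threshold plus one refill interval, so the stitched
   episodes recover the latent ones by construction (exactly, when dosing
   instructions are complete).

Episodes are censored at de-registration and at the end of the data window.
No prescribing occurs before the 14th birthday while ``enforce_min_age`` is
set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date, timedelta

import numpy as np
import pandas as pd

from ._dates import add_years, days_in_year, to_date, year_start_ordinal
from .config import ConfigError, SimulationConfig, year_value

__all__ = [
    "SimulationTruth",
    "generate_population",
    "generate_prescriptions",
    "simulate_study",
    "write_tables",
]

# product frequency tables per class: (name, weight, unit strength mg)
_SSRI = [
    ("fluoxetine", 0.35, 20.0),
    ("citalopram", 0.30, 20.0),
    ("sertraline", 0.20, 50.0),
    ("paroxetine", 0.15, 20.0),
]
# non-low-dose TCA mix; amitriptyline appears again at low dose via
# ``low_dose_amitriptyline_rate``
_TCA = [
    ("amitriptyline", 0.27, 75.0),
    ("dosulepin", 0.30, 75.0),
    ("lofepramine", 0.20, 70.0),
    ("imipramine", 0.13, 50.0),
    ("clomipramine", 0.10, 75.0),
]
_OTHER = [
    ("mirtazapine", 0.42, 30.0),
    ("venlafaxine", 0.36, 75.0),
    ("trazodone", 0.12, 150.0),
    ("duloxetine", 0.06, 60.0),
    ("reboxetine", 0.04, 8.0),
]
_LOW_DOSE_AMI_STRENGTHS = (10.0, 25.0)

#: upper bound on any 4-calendar-month span, in days
_FOUR_MONTHS_MAX_DAYS = 123


@dataclass
class SimulationTruth:
    """Latent generating state paired with a generated dataset."""

    episodes: pd.DataFrame  # one row per latent treatment episode
    depression_flags: pd.Series  # patient_id -> bool
    config_fingerprint: str


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed) % (2**31), stream]))


def generate_population(config: SimulationConfig) -> pd.DataFrame:
    """Generate the patient table.

    Registration intervals are recorded clipped to the data window (the
    convention of an extract whose observation starts at ``data_start``); a
    missing ``reg_end`` means still registered at ``data_end``.  Deterministic
    given ``config.seed``.
    """
    rng = _rng(config, 0)
    n = config.n_patients
    d0 = to_date(config.data_start)
    d1 = to_date(config.data_end)
    e0 = to_date(config.earliest_entry)

    rows = []
    for i in range(n):
        pid = f"P{i:06d}"
        sex = "F" if rng.random() < config.sex_ratio else "M"
        by = int(rng.integers(config.birth_year_min, config.birth_year_max + 1))
        birth = date.fromordinal(
            year_start_ordinal(by) + int(rng.integers(0, days_in_year(by)))
        )
        if rng.random() < config.pre_window_fraction:
            entry_ord = int(rng.integers(e0.toordinal(), d0.toordinal()))
        else:
            entry_ord = int(rng.integers(d0.toordinal(), d1.toordinal()))
        entry_ord = max(entry_ord, birth.toordinal() + 1)
        reg_start = date.fromordinal(max(entry_ord, d0.toordinal()))  # clip to window
        if config.exit_hazard_per_year > 0:
            stay_days = rng.exponential(365.25 / config.exit_hazard_per_year)
        else:
            stay_days = math.inf
        # exit is memoryless, so the residual stay of patients already
        # registered when the window opens is drawn from the window start
        end_ord = max(entry_ord, d0.toordinal()) + int(stay_days)
        reg_end = date.fromordinal(end_ord) if end_ord <= d1.toordinal() else None
        if reg_end is not None and reg_end <= reg_start:
            reg_end = reg_start + timedelta(days=1)
        acceptable = bool(rng.random() < config.acceptable_rate)
        rows.append((pid, sex, birth, reg_start, reg_end, acceptable, False))

    patients = pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "sex",
            "birth_date",
            "reg_start",
            "reg_end",
            "acceptable",
            "depression_flag",
        ],
    )
    patients.attrs["sim_fingerprint"] = config.fingerprint()
    return patients


def _sex_multiplier(config: SimulationConfig, sex: str, year: int) -> float:
    r = float(year_value(config.female_hazard_ratio, year))
    return 2.0 * r / (r + 1.0) if sex == "F" else 2.0 / (r + 1.0)


def _draw_event(rng, t0: int, t1: int, rate_of_year) -> int | None:
    """First event ordinal in [t0, t1) under a piecewise-constant yearly hazard."""
    if t1 <= t0:
        return None
    target = rng.exponential()
    cum = 0.0
    t = t0
    while t < t1:
        y = date.fromordinal(t).year
        chunk_end = min(year_start_ordinal(y + 1), t1)
        lam = float(rate_of_year(y))  # per person-year
        frac = (chunk_end - t) / days_in_year(y)
        if lam > 0 and cum + lam * frac >= target:
            pos_years = (target - cum) / lam
            event = t + int(pos_years * days_in_year(y))
            return min(event, t1 - 1)
        cum += lam * frac
        t = chunk_end
    return None


def _draw_product(rng, drug_class: str, config: SimulationConfig):
    """Return (product_name, daily_dose_mg, units_per_day) for a new episode."""
    units = 2 if rng.random() < 0.3 else 1
    if drug_class == "TCA" and rng.random() < config.low_dose_amitriptyline_rate:
        strength = float(rng.choice(_LOW_DOSE_AMI_STRENGTHS))
        return "amitriptyline", strength * units, units
    table = {"SSRI": _SSRI, "TCA": _TCA, "OTHER": _OTHER}[drug_class]
    weights = np.array([w for _, w, _ in table])
    idx = int(rng.choice(len(table), p=weights / weights.sum()))
    name, _, strength = table[idx]
    return name, strength * units, units


def generate_prescriptions(
    patients: pd.DataFrame, config: SimulationConfig
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Generate the therapy table and latent truth for ``patients``.

    ``patients`` must come from :func:`generate_population` with the same
    configuration (checked via a fingerprint).  Deterministic given
    ``config.seed``.
    """
    fp = patients.attrs.get("sim_fingerprint")
    if fp is not None and fp != config.fingerprint():
        raise ConfigError("patients table was generated with a different configuration")
    if len(patients) != config.n_patients:
        raise ConfigError(
            f"patients table has {len(patients)} rows but config.n_patients is {config.n_patients}"
        )
    rng = _rng(config, 1)
    d0 = to_date(config.data_start).toordinal()
    d1 = to_date(config.data_end).toordinal() + 1  # half-open window end
    gap_guard = _FOUR_MONTHS_MAX_DAYS + config.refill_interval_days + 7
    class_names = ("SSRI", "TCA", "OTHER")

    rx_rows, ep_rows = [], []
    for p in patients.itertuples(index=False):
        birth = to_date(p.birth_date)
        w0 = max(to_date(p.reg_start).toordinal(), d0)
        if config.enforce_min_age:
            w0 = max(w0, add_years(birth, 14).toordinal())
        w1 = d1 if pd.isna(p.reg_end) else min(to_date(p.reg_end).toordinal(), d1)

        t = w0
        ep_index = 0
        while t < w1:
            mult = 1.0 if ep_index == 0 else config.restart_hazard_multiplier

            def rate(year, _m=mult, _s=p.sex):
                base = float(year_value(config.start_hazard_per_1000py, year)) / 1000.0
                return base * _m * _sex_multiplier(config, _s, year)

            start = _draw_event(rng, t, w1, rate)
            if start is None:
                break
            year = date.fromordinal(start).year
            mix = np.asarray(year_value(config.class_mix, year), dtype=float)
            drug_class = class_names[int(rng.choice(3, p=mix / mix.sum()))]
            product, dose, units = _draw_product(rng, drug_class, config)
            median = float(year_value(config.episode_median_days, year))
            intended = max(1, int(round(rng.lognormal(math.log(median), config.episode_log_sigma))))
            end = min(start + intended, w1)
            n_scripts = 0
            pos = start
            while pos < end:
                cover = min(config.refill_interval_days, end - pos)
                missing = rng.random() < config.missing_instruction_rate
                rx_rows.append(
                    (
                        p.patient_id,
                        date.fromordinal(pos),
                        product,
                        dose,
                        int(units * cover),
                        np.nan if missing else float(units),
                    )
                )
                n_scripts += 1
                pos += config.refill_interval_days
            ep_rows.append(
                (
                    p.patient_id,
                    ep_index,
                    date.fromordinal(start),
                    date.fromordinal(end),
                    end - start,
                    intended,
                    drug_class,
                    product,
                    n_scripts,
                    ep_index == 0,
                )
            )
            ep_index += 1
            t = end + gap_guard
    therapy = pd.DataFrame(
        rx_rows,
        columns=[
            "patient_id",
            "issue_date",
            "product_name",
            "daily_dose_mg",
            "quantity",
            "units_per_day",
        ],
    )
    truth_eps = pd.DataFrame(
        ep_rows,
        columns=[
            "patient_id",
            "episode_index",
            "start_date",
            "end_date",
            "duration_days",
            "intended_duration_days",
            "drug_class",
            "product_name",
            "n_prescriptions",
            "first_ever",
        ],
    )
    users = set(truth_eps["patient_id"].unique()) if not truth_eps.empty else set()
    flags = {}
    for pid in patients["patient_id"]:
        rate_ = config.depression_flag_rate if pid in users else config.background_depression_rate
        flags[pid] = bool(rng.random() < rate_)
    truth = SimulationTruth(
        episodes=truth_eps,
        depression_flags=pd.Series(flags, name="depression_flag"),
        config_fingerprint=config.fingerprint(),
    )
    return therapy, truth


def simulate_study(config: SimulationConfig):
    """Generate (patients, therapy, truth) in one call, with depression flags applied."""
    patients = generate_population(config)
    therapy, truth = generate_prescriptions(patients, config)
    patients = patients.copy()
    patients["depression_flag"] = patients["patient_id"].map(truth.depression_flags).astype(bool)
    patients.attrs["sim_fingerprint"] = config.fingerprint()
    return patients, therapy, truth


def write_tables(out_dir, patients: pd.DataFrame, therapy: pd.DataFrame, truth=None) -> dict:
    """Write the generated tables as comma-separated text with ISO-8601 dates."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"patients": out / "patients.csv", "therapy": out / "therapy.csv"}
    patients.to_csv(paths["patients"], index=False)
    therapy.to_csv(paths["therapy"], index=False)
    if truth is not None:
        paths["truth_episodes"] = out / "truth_episodes.csv"
        truth.episodes.to_csv(paths["truth_episodes"], index=False)
    return paths
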