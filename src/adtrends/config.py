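"""Study and simulation configuration.

Two dataclasses drive every stage of the pipeline:

* :class:`StudyConfig` — the analytic rules of the drug-utilisation study:
  study window, minimum age, registration lookback, the episode-stitching gap,
  and the duration categories.
* :class:`SimulationConfig` — the generating process for the synthetic
  primary-care dataset (cohort composition, per-year starting hazards, drug
  class mix, episode-length distributions, refill cadence, missingness).

Both can be loaded from a single declarative YAML file with ``study:`` and
``simulation:`` sections (see :func:`load_config`).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date
from typing import Mapping, Sequence

import yaml

from ._dates import to_date

__all__ = [
    "ConfigError",
    "StudyConfig",
    "SimulationConfig",
    "year_value",
    "interpolate_year_map",
    "load_config",
]


class ConfigError(ValueError):
    """Invalid configuration; the message names the offending field."""


def interpolate_year_map(anchors: Mapping[int, float], years: Sequence[int]) -> dict[int, float]:
    """Linear interpolation of anchor values onto every year in ``years``.

    Years outside the anchor range take the nearest anchor value.
    """
    ay = sorted(anchors)
    out: dict[int, float] = {}
    for y in years:
        if y <= ay[0]:
            out[y] = float(anchors[ay[0]])
        elif y >= ay[-1]:
            out[y] = float(anchors[ay[-1]])
        else:
            for lo, hi in zip(ay, ay[1:]):
                if lo <= y <= hi:
                    w = (y - lo) / (hi - lo)
                    out[y] = float((1 - w) * anchors[lo] + w * anchors[hi])
                    break
    return out


def year_value(mapping: Mapping[int, float] | float, year: int):
    """Look up a per-year parameter, clamping to the nearest covered year."""
    if not isinstance(mapping, Mapping):
        return mapping
    if year in mapping:
        return mapping[year]
    ys = sorted(mapping)
    if year < ys[0]:
        return mapping[ys[0]]
    return mapping[ys[-1]]


@dataclass(frozen=True)
class StudyConfig:
    """Analytic rules for the prescribing-trend study.

    Defaults encode the study design this package implements: prescriptions
    extracted from 1992, rates reported for 1995-2011, patients aged >=14 with
    at least 3 years' registration, a 4-calendar-month refill gap closing a
    treatment episode, and six duration categories with cut points at
    30/60/180/365/730 days.
    """

    extraction_start: date = date(1992, 1, 1)
    study_start_year: int = 1995
    study_end_year: int = 2011
    min_age_years: int = 14
    lookback_years: int = 3
    gap_months: int = 4
    #: if set, use a fixed gap in days instead of calendar months
    gap_days: int | None = None
    duration_last_start_year: int = 2009
    duration_bins_days: tuple[int, ...] = (30, 60, 180, 365, 730)
    #: ages at which the age band changes; bands are <18, 18-30, 31-45, 46-60,
    #: 61-75, 76+ by default (first boundary fixed by the under-18 stratum)
    age_band_edges: tuple[int, ...] = (18, 31, 46, 61, 76)
    #: apply the 3-year registration rule to person-time denominators as well
    #: as to event numerators
    require_lookback_for_person_time: bool = True
    #: low-dose amitriptyline sensitivity: drop flagged prescriptions
    #: ("prescription") or whole patients all of whose scripts are flagged
    #: ("patient")
    low_dose_exclusion_level: str = "prescription"

    def __post_init__(self) -> None:
        if self.study_end_year < self.study_start_year:
            raise ConfigError(
                f"study_end_year ({self.study_end_year}) < study_start_year "
                f"({self.study_start_year})"
            )
        if to_date(self.extraction_start).year > self.study_start_year:
            raise ConfigError("extraction_start must not be after the study start year")
        if self.lookback_years < 0:
            raise ConfigError("lookback_years must be >= 0")
        if self.min_age_years < 0:
            raise ConfigError("min_age_years must be >= 0")
        if self.gap_months <= 0:
            raise ConfigError("gap_months must be positive")
        if self.gap_days is not None and self.gap_days <= 0:
            raise ConfigError("gap_days must be positive when set")
        bins = tuple(self.duration_bins_days)
        if any(b <= a for a, b in zip(bins, bins[1:])) or (bins and bins[0] < 1):
            raise ConfigError("duration_bins_days must be strictly increasing positive cut points")
        edges = tuple(self.age_band_edges)
        if any(b <= a for a, b in zip(edges, edges[1:])):
            raise ConfigError("age_band_edges must be strictly increasing")
        if self.low_dose_exclusion_level not in ("prescription", "patient"):
            raise ConfigError("low_dose_exclusion_level must be 'prescription' or 'patient'")

    @property
    def study_years(self) -> range:
        return range(self.study_start_year, self.study_end_year + 1)


def _default_start_hazard() -> dict[int, float]:
    # first-ever starting hazard per 1000 PY: slow decline with a dip after
    # 2002 and partial recovery after 2005
    return interpolate_year_map(
        {1992: 21.0, 1995: 21.3, 2002: 22.5, 2005: 16.5, 2008: 17.0, 2011: 17.9},
        range(1992, 2012),
    )


def _default_female_ratio() -> dict[int, float]:
    # female:male starting-hazard ratio narrowing over the study window
    return interpolate_year_map({1992: 2.0, 1995: 1.9, 2011: 1.2}, range(1992, 2012))


def _default_class_mix() -> dict[int, tuple[float, float, float]]:
    # (SSRI, TCA, OTHER) probabilities per start year: SSRIs displace TCAs
    ssri = interpolate_year_map({1992: 0.34, 2002: 0.52, 2011: 0.56}, range(1992, 2012))
    other = interpolate_year_map({1992: 0.07, 2002: 0.09, 2011: 0.16}, range(1992, 2012))
    return {y: (ssri[y], 1.0 - ssri[y] - other[y], other[y]) for y in range(1992, 2012)}


def _default_episode_median() -> dict[int, float]:
    # median intended episode length (days) by start year, lengthening with
    # later starts
    return interpolate_year_map({1992: 42.0, 1995: 44.0, 2009: 56.0, 2011: 60.0}, range(1992, 2012))


@dataclass(frozen=True)
class SimulationConfig:
    """Generating process for the synthetic primary-care cohort.

    The defaults are the package's reference study conditions: a 1992-2011
    data window, a first-ever starting hazard around 17-22 per 1000 PY, a drug
    class mix shifting from tricyclics towards SSRIs, a female:male starting
    ratio narrowing from ~1.9 to ~1.2, log-normal episode lengths whose median
    grows from 44 to 56 days over 1995-2009, 28-day repeat prescriptions, and
    a fifth of prescriptions missing their dosing instruction.
    """

    n_patients: int = 10_000
    data_start: date = date(1992, 1, 1)
    data_end: date = date(2011, 12, 31)

    # registration model
    #: fraction of patients already registered before data_start
    pre_window_fraction: float = 0.55
    earliest_entry: date = date(1975, 1, 1)
    exit_hazard_per_year: float = 0.06

    # age / sex model
    birth_year_min: int = 1915
    birth_year_max: int = 1995
    sex_ratio: float = 0.51  # fraction female

    # prescribing process
    start_hazard_per_1000py: Mapping[int, float] = field(default_factory=_default_start_hazard)
    female_hazard_ratio: Mapping[int, float] | float = field(default_factory=_default_female_ratio)
    restart_hazard_multiplier: float = 2.0
    class_mix: Mapping[int, tuple[float, float, float]] = field(default_factory=_default_class_mix)
    episode_median_days: Mapping[int, float] = field(default_factory=_default_episode_median)
    episode_log_sigma: float = 1.8
    refill_interval_days: int = 28
    missing_instruction_rate: float = 0.2
    depression_flag_rate: float = 0.67
    #: depression-flag rate among patients never prescribed an antidepressant
    background_depression_rate: float = 0.05
    #: fraction of TCA prescriptions that are amitriptyline below 75 mg/day
    low_dose_amitriptyline_rate: float = 0.4
    acceptable_rate: float = 1.0
    #: suppress prescribing before the 14th birthday
    enforce_min_age: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ConfigError("n_patients must be >= 0")
        if to_date(self.data_start) >= to_date(self.data_end):
            raise ConfigError("data_start must be before data_end")
        for name in (
            "pre_window_fraction",
            "sex_ratio",
            "missing_instruction_rate",
            "depression_flag_rate",
            "background_depression_rate",
            "low_dose_amitriptyline_rate",
            "acceptable_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if self.exit_hazard_per_year < 0:
            raise ConfigError("exit_hazard_per_year must be >= 0")
        if self.restart_hazard_multiplier < 0:
            raise ConfigError("restart_hazard_multiplier must be >= 0")
        if self.refill_interval_days <= 0:
            raise ConfigError("refill_interval_days must be positive")
        if self.episode_log_sigma <= 0:
            raise ConfigError("episode_log_sigma must be positive")
        if self.birth_year_max < self.birth_year_min:
            raise ConfigError("birth_year_max must be >= birth_year_min")
        for y, h in dict(self.start_hazard_per_1000py).items():
            if h < 0:
                raise ConfigError(f"start_hazard_per_1000py[{y}] must be >= 0, got {h}")
        for y, mix in dict(self.class_mix).items():
            if len(mix) != 3 or any(p < 0 for p in mix):
                raise ConfigError(f"class_mix[{y}] must be three non-negative probabilities")
            if abs(sum(mix) - 1.0) > 1e-9:
                raise ConfigError(f"class_mix[{y}] must sum to 1 (got {sum(mix)!r})")
        for y, m in dict(self.episode_median_days).items():
            if m <= 0:
                raise ConfigError(f"episode_median_days[{y}] must be positive, got {m}")

    def fingerprint(self) -> str:
        """Stable digest of the configuration, used to pair generated tables."""
        import hashlib

        payload = repr(sorted(_as_plain(self).items())).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _as_plain(cfg) -> dict:
    out = {}
    for f in dataclasses.fields(cfg):
        v = getattr(cfg, f.name)
        if isinstance(v, Mapping):
            v = {k: (tuple(x) if isinstance(x, (list, tuple)) else x) for k, x in sorted(v.items())}
        elif isinstance(v, date):
            v = v.isoformat()
        out[f.name] = v
    return out


def _coerce(cls, raw: dict):
    """Build a config dataclass from a plain dict (e.g. parsed YAML)."""
    known = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, val in raw.items():
        if key not in known:
            raise ConfigError(f"unknown {cls.__name__} field: {key}")
        name = key
        if name in ("extraction_start", "data_start", "data_end", "earliest_entry"):
            val = to_date(val)
        elif isinstance(val, dict):
            val = {
                int(k): (tuple(v) if isinstance(v, (list, tuple)) else float(v))
                for k, v in val.items()
            }
        elif isinstance(val, list):
            val = tuple(val)
        kwargs[name] = val
    return cls(**kwargs)


def load_config(path) -> dict:
    """Read a declarative YAML run configuration.

    Returns a dict with keys ``study`` (:class:`StudyConfig`), ``simulation``
    (:class:`SimulationConfig` or ``None``) and ``run`` (remaining top-level
    options such as ``simulate``, ``strata`` or sensitivity toggles).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("configuration file must contain a mapping")
    study = _coerce(StudyConfig, raw.get("study", {}) or {})
    sim_raw = raw.get("simulation")
    simulation = _coerce(SimulationConfig, sim_raw) if sim_raw is not None else None
    run = {k: v for k, v in raw.items() if k not in ("study", "simulation")}
    return {"study": study, "simulation": simulation, "run": run}
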