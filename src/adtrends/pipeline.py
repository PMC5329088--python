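"""End-to-end orchestration: simulate/load -> classify -> episodes -> rates -> trends.

A single declarative YAML configuration drives a run.  Every stage is logged
with record counts in and out (so eligibility and sensitivity filters are
auditable) and all tabular outputs are comma-separated text with ISO-8601
dates.  A run manifest captures the configuration snapshot, the seed, and a
SHA-256 digest of every output file: re-running with an identical
configuration reproduces byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from datetime import date
from pathlib import Path

import pandas as pd

from . import __version__
from ._dates import to_date
from .cohort import build_person_time_table
from .config import ConfigError, SimulationConfig, StudyConfig, load_config
from .drugs import ProductDictionary, classify_table
from .episodes import build_episodes, compute_product_medians, flag_incident
from .rates import (
    apply_sensitivity,
    duration_trend,
    incidence,
    period_prevalence,
    sex_ratio_series,
)
from .synthetic import simulate_study, write_tables
from .trends import select_joinpoints

__all__ = ["run_pipeline", "validate_inputs", "read_patients", "read_therapy"]

log = logging.getLogger("adtrends")

PATIENT_COLUMNS = ["patient_id", "sex", "birth_date", "reg_start", "reg_end"]
THERAPY_REQUIRED = ["patient_id", "issue_date", "product_name", "quantity"]


def read_patients(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("birth_date", "reg_start", "reg_end"):
        if col in df:
            df[col] = pd.to_datetime(df[col], errors="coerce")
    if "acceptable" not in df:
        df["acceptable"] = True
    if "depression_flag" not in df:
        df["depression_flag"] = False
    return df


def read_therapy(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "issue_date" in df:
        df["issue_date"] = pd.to_datetime(df["issue_date"], errors="coerce")
    if "units_per_day" not in df:
        df["units_per_day"] = pd.NA
    if "daily_dose_mg" not in df:
        df["daily_dose_mg"] = pd.NA
    return df


def validate_inputs(patient_file, therapy_file) -> pd.DataFrame:
    """Schema validation report; never repairs anything.

    Returns one row per violation with columns ``table, row, problem`` (row
    numbers are 0-based data rows).  An empty frame means the inputs are
    well formed.
    """
    problems: list[tuple[str, int, str]] = []

    patients = pd.read_csv(patient_file)
    therapy = pd.read_csv(therapy_file)

    for col in PATIENT_COLUMNS:
        if col not in patients.columns:
            problems.append(("patients", -1, f"missing column {col!r}"))
    for col in THERAPY_REQUIRED:
        if col not in therapy.columns:
            problems.append(("therapy", -1, f"missing column {col!r}"))
    if any(r == -1 for _, r, _ in problems):
        return pd.DataFrame(problems, columns=["table", "row", "problem"])

    for col in ("birth_date", "reg_start", "reg_end"):
        parsed = pd.to_datetime(patients[col], errors="coerce")
        bad = patients[col].notna() & parsed.isna()
        problems += [("patients", int(i), f"unparseable date in {col!r}") for i in patients.index[bad]]
        patients[col] = parsed
    parsed = pd.to_datetime(therapy["issue_date"], errors="coerce")
    bad = therapy["issue_date"].notna() & parsed.isna()
    problems += [("therapy", int(i), "unparseable date in 'issue_date'") for i in therapy.index[bad]]
    therapy["issue_date"] = parsed

    qty = pd.to_numeric(therapy["quantity"], errors="coerce")
    for i in therapy.index[qty.isna() | (qty <= 0)]:
        problems.append(("therapy", int(i), "quantity must be a positive number"))

    closed = patients["reg_end"].notna()
    for i in patients.index[closed & (patients["reg_end"] <= patients["reg_start"])]:
        problems.append(("patients", int(i), "reg_end not after reg_start"))
    for i in patients.index[patients["birth_date"] >= patients["reg_start"]]:
        problems.append(("patients", int(i), "birth_date not before reg_start"))

    reg = patients.set_index("patient_id")
    for i, row in therapy.iterrows():
        pid = row["patient_id"]
        if pid not in reg.index:
            problems.append(("therapy", int(i), f"unknown patient_id {pid!r}"))
            continue
        if pd.isna(row["issue_date"]):
            continue
        start = reg.at[pid, "reg_start"]
        end = reg.at[pid, "reg_end"]
        if pd.notna(start) and row["issue_date"] < start:
            problems.append(("therapy", int(i), "prescription issued before reg_start"))
        elif pd.notna(end) and row["issue_date"] > end:
            problems.append(("therapy", int(i), "prescription issued after reg_end"))
    return pd.DataFrame(problems, columns=["table", "row", "problem"])


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _jsonable(obj):
    if dataclasses.is_dataclass(obj):
        return {f.name: _jsonable(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, date):
        return obj.isoformat()
    return obj


def run_pipeline(config_path, output_dir) -> dict:
    """Run the full analysis described by a YAML configuration file.

    Returns the run manifest (also written to ``manifest.json``).
    """
    cfg = load_config(config_path)
    study: StudyConfig = cfg["study"]
    sim: SimulationConfig | None = cfg["simulation"]
    run = cfg["run"]
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    def save(name: str, df: pd.DataFrame):
        path = out / f"{name}.csv"
        df.to_csv(path, index=False)
        written[name] = path
        return path

    # --- inputs -----------------------------------------------------------
    if run.get("simulate", sim is not None):
        if sim is None:
            raise ConfigError("simulate: true requires a simulation section")
        log.info("simulating cohort: %d patients, seed %d", sim.n_patients, sim.seed)
        patients, therapy, truth = simulate_study(sim)
        paths = write_tables(out, patients, therapy, truth)
        written.update({k: Path(v) for k, v in paths.items()})
    else:
        patient_file = run.get("patient_file")
        therapy_file = run.get("therapy_file")
        if not patient_file or not therapy_file:
            raise ConfigError("patient_file and therapy_file are required when simulate is false")
        report = validate_inputs(patient_file, therapy_file)
        if not report.empty:
            save("validation_report", report)
            raise ValueError(
                f"input validation failed with {len(report)} problem(s); "
                f"see validation_report.csv (first: {report.iloc[0].to_dict()})"
            )
        patients = read_patients(patient_file)
        therapy = read_therapy(therapy_file)
    log.info("stage inputs: %d patients, %d prescriptions", len(patients), len(therapy))

    # --- classification ---------------------------------------------------
    dict_path = run.get("product_dictionary")
    dictionary = ProductDictionary.from_csv(dict_path) if dict_path else ProductDictionary.packaged()
    therapy = classify_table(therapy, dictionary)

    # --- person-time ------------------------------------------------------
    person_time = {s: build_person_time_table(patients, study, s) for s in ("none", "sex", "age_band")}
    for name, table in person_time.items():
        save(f"person_time_{name}", table)
    log.info(
        "stage person-time: %.1f PY total", person_time["none"]["person_years"].sum()
    )

    # --- episodes ---------------------------------------------------------
    medians = compute_product_medians(therapy)
    episodes = flag_incident(build_episodes(therapy, study, medians), patients, study)
    save("episodes", episodes)
    log.info(
        "stage episodes: %d episodes (%d incident) from %d prescriptions",
        len(episodes),
        int(episodes["incident"].sum()) if len(episodes) else 0,
        len(therapy),
    )

    # --- rates ------------------------------------------------------------
    strata = run.get("strata", ["none", "sex", "age_band", "drug_class"])
    prev = {}
    inc = {}
    for s in strata:
        pt = person_time["none"] if s == "drug_class" else person_time[s]
        prev[s] = period_prevalence(therapy, pt, patients, study, s)
        save(f"prevalence_{s}", prev[s])
        inc[s] = incidence(episodes, pt, patients, study, s)
        save(f"incidence_{s}", inc[s])
    if "sex" in strata:
        ratios, trend_test = sex_ratio_series(prev["sex"])
        save("fm_ratio", ratios)
        (out / "fm_ratio_trend_test.json").write_text(json.dumps(trend_test, indent=2))
        written["fm_ratio_trend_test"] = out / "fm_ratio_trend_test.json"

    dur = duration_trend(episodes, study)
    save("duration_proportions", dur["proportions"])
    save("duration_medians", dur["medians"])

    # --- sensitivity ------------------------------------------------------
    for mode in run.get("sensitivity", ["exclude_low_dose_ami", "depression_subgroup"]):
        rx_s, pats_s = apply_sensitivity(therapy, patients, mode, study)
        pt_s = build_person_time_table(pats_s, study, "none")
        eps_s = flag_incident(build_episodes(rx_s, study), pats_s, study)
        save(f"prevalence_{mode}", period_prevalence(rx_s, pt_s, pats_s, study, "none"))
        save(f"incidence_{mode}", incidence(eps_s, pt_s, pats_s, study, "none"))
        log.info(
            "stage sensitivity %s: %d -> %d prescriptions, %d -> %d patients",
            mode, len(therapy), len(rx_s), len(patients), len(pats_s),
        )

    # --- trends -----------------------------------------------------------
    max_jp = int(run.get("max_joinpoints", 4))
    seed = int(run.get("trend_seed", sim.seed if sim else 0))
    fits = {}
    for name, series in (("prevalence", prev.get("none")), ("incidence", inc.get("none"))):
        if series is None or (series["rate_per_1000py"] <= 0).any():
            continue
        fit = select_joinpoints(series, max_joinpoints=max_jp, seed=seed)
        fits[name] = fit
        (out / f"trend_{name}.txt").write_text(fit.summary() + "\n")
        written[f"trend_{name}"] = out / f"trend_{name}.txt"

    # --- figures ----------------------------------------------------------
    from . import plotting

    figdir = out / "figures"
    figdir.mkdir(exist_ok=True)
    for s in strata:
        plot_src = prev.get(s)
        if plot_src is not None and len(plot_src):
            plotting.plot_rate_series(
                plot_src, figdir / f"prevalence_{s}.png", title=f"period prevalence ({s})"
            )
    if inc.get("none") is not None and len(inc["none"]):
        plotting.plot_rate_series(inc["none"], figdir / "incidence.png", title="incidence")
    if len(dur["proportions"]):
        plotting.plot_duration_proportions(dur["proportions"], figdir / "duration_proportions.png")
        plotting.plot_median_duration(dur["medians"], figdir / "duration_medians.png")

    # --- manifest ---------------------------------------------------------
    manifest = {
        "adtrends_version": __version__,
        "seed": sim.seed if sim else None,
        "study_config": _jsonable(study),
        "simulation_config": _jsonable(sim) if sim else None,
        "run_options": _jsonable(run),
        "outputs": {
            name: {"path": str(p.relative_to(out)), "sha256": _digest(p)}
            for name, p in sorted(written.items())
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    log.info("wrote %d outputs to %s", len(written), out)
    return manifest
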