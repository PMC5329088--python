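"""The README worked example: simulate a small cohort and print its trends."""

from adtrends import (
    SimulationConfig,
    StudyConfig,
    simulate_study,
    build_person_time_table,
    build_episodes,
    flag_incident,
    period_prevalence,
    incidence,
    select_joinpoints,
    duration_trend,
)
from adtrends.drugs import classify_table

study = StudyConfig()  # 1995-2011, age >=14, 3-year lookback, 4-month gap
sim = SimulationConfig(n_patients=5000, seed=42)
patients, therapy, truth = simulate_study(sim)
therapy = classify_table(therapy)  # attach SSRI/TCA/OTHER labels
episodes = flag_incident(build_episodes(therapy, study), patients, study)
py = build_person_time_table(patients, study)
prev = period_prevalence(therapy, py, patients, study)
inc = incidence(episodes, py, patients, study)

print(
    f"{len(therapy)} prescriptions -> {len(episodes)} episodes "
    f"({episodes['incident'].sum()} incident)"
)
for y in (1995, 2003, 2011):
    p = prev.set_index("year").loc[y]
    i = inc.set_index("year").loc[y]
    print(
        f"{y}: prevalence {p.rate_per_1000py:5.1f}/1000 PY  "
        f"incidence {i.rate_per_1000py:5.1f}/1000 PY  ({p.person_years:.0f} PY)"
    )
fit = select_joinpoints(prev, max_joinpoints=3)
print(fit.summary())
meds = duration_trend(episodes, study)["medians"].set_index("start_year")
print(
    f"median incident episode length: {meds.loc[1995, 'median_duration_days']:.0f} d (1995) "
    f"-> {meds.loc[2009, 'median_duration_days']:.0f} d (2009)"
)
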