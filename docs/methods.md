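# Methods

This note documents the analytic rules the package implements, the choices
made where the design was genuinely open, the generating process behind the
synthetic data, and what the verification experiments do and do not
establish.

## Cohort and person-time

Patients enter analysis when three conditions hold simultaneously: an
acceptable record, age at or above `min_age_years` (default 14, since
antidepressant prescribing in younger children is rare), and a registration
history of at least `lookback_years` (default 3) calendar years. The
registration rule is enforced as a date, not a filter: a patient contributes
person-time and events only from the anniversary at which they have 3
years' history, which reconciles the cohort-level "registered at least 3
years" statement with the per-event rule that a prescription in July 2000
requires registration since July 1997. A configuration toggle
(`require_lookback_for_person_time`) relaxes the rule for denominators only,
for users who prefer an unconditional prevalence denominator.

All intervals are half-open `[start, end)` at day resolution, which makes
person-time additive with no double counting at year boundaries. A year's
denominator divides overlap days by the year's actual length (366 in leap
years). Consequently the canonical "3 months then left" example evaluates
to 91/365 ≈ 0.2493 rather than exactly 0.25: calendar quarters are not
exactly a quarter of a year in days. Tests assert the value to within one
day (1/365).

Age changes mid-year split person-time at the birthday, both for the
minimum-age filter and for age-band stratification, so every day of
person-time sits in the band containing the patient's age that day. The
first band boundary (18) is fixed by the under-18 stratum of interest; the
remaining boundaries (31, 46, 61, 76) are conventional and configurable.

## Episodes

Each prescription's intended duration is `quantity / units_per_day`, rounded
half-up with a floor of one day. When the dosing instruction is missing the
product-level median duration-per-script (over instruction-complete scripts)
is imputed, falling back to the global median across products.

Stitching is greedy left-to-right per patient: a running expected end is
maintained as `max(previous end, issue + duration)`, and a new episode opens
when the next issue date falls on or after the expected end plus the gap
threshold. The threshold is 4 *calendar* months by default (stated in
months, implemented with end-of-month clamping); `gap_days` substitutes a
fixed day count for sensitivity work (e.g. 30 days or 6 months ≈ 183 days).
Two deliberate choices:

* **Overlaps extend, they do not sum.** A script issued while the previous
  one still runs extends the expected end to the later of the two; no
  stockpiling is assumed. Episode duration is therefore the calendar span
  of the stitched interval, the conservative standard in refill-gap episode
  construction.
* **Cross-product stitching.** Consecutive scripts need not share a product
  or class; an episode records the union of classes present and the class
  of its first script.

Episodes are censored at the end of the data window. Duration-trend tables
use only incident episodes starting up to `duration_last_start_year`
(default 2009, i.e. two years before the data end), so the longest duration
category (731+ days) remains attainable for every start year analysed.

Greedy stitching is provably equivalent to the transitive closure of the
pairwise gap rule on date-sorted scripts, because the month-offset function
is monotone; the test suite nevertheless checks exact agreement with an
O(n²) union-find oracle on 1000 random streams, since this equivalence is
the part of the pipeline easiest to break silently.

An episode is **incident** iff it is the patient's first-ever episode in the
extracted data and the lookback condition holds at its start. First
episodes without lookback are excluded from incidence numerators entirely
rather than deferred.

## Rates

Period prevalence counts distinct patients with at least one prescription
issued in the calendar year (per class when stratified, so a patient may
count once in each of several classes); a multi-year episode contributes
the patient only to years in which a script was actually issued. Incidence
counts incident episode starts. Both report `1000 × numerator /
person-years` and the implementation re-derives the rate from the stored
numerator and denominator columns, so the identity is checkable on every
output row.

The denominator for incidence is the caller's choice. The standard table
(all eligible person-time) gives rates on the same footing as prevalence,
which is how population drug-utilisation studies usually report them. A
table censored at each patient's first-ever prescription gives drug-naive
person-time, which is the unbiased estimator of the *starting hazard*: with
a fixed cohort, the naive fraction depletes over time, so rates on the
total denominator drift a few percent below the generating hazard in late
years. The verification experiments use the naive denominator precisely
because their estimand is the generator's hazard parameter; the pipeline
default remains the standard table.

The female:male trend test is the textbook Cochran–Armitage chi-square for
linear trend with calendar-year scores applied to the per-year
(female, male) event counts; it is cross-checked in the tests against the
score-correlation identity χ² = N·r² and carries no bespoke inference.

## Segmented trends

Rate series are fitted on the log scale with the hinge parameterisation
`ln r(y) = a + b0·y + Σ ck·max(0, y − τk)`, which enforces continuity at
the change points by construction. Candidate joinpoints are integer interior
years with at least `min_per_segment` (default 2) observations per segment;
all combinations up to `max_joinpoints` are fitted by unweighted least
squares. Model selection is by BIC with `2 + 2k` parameters for k
joinpoints (each joinpoint contributes a location and a slope change); the
residual sum of squares is floored at 1e-12 so that numerically exact fits
tie and the tie breaks towards fewer joinpoints. An alternative sequential
Monte-Carlo permutation test (499 permutations of the simpler model's
residuals, α = 0.05, deterministic given a seed) is provided. Per-segment
slopes b are reported as annual percentage changes, `APC = 100·(e^b − 1)`.

This is an approximation in the joinpoint-regression family, not a
re-implementation of any particular software: it uses unweighted log-scale
least squares, integer-year breaks, and information-criterion selection,
and it does not produce confidence intervals for joinpoint years.
Nonpositive rates are rejected with instructions to offset or drop, rather
than silently adjusted.

## Synthetic data generator

The generator emulates a primary-care extract over 1992–2011 with study
years 1995–2011. Reference (default) conditions, chosen once:

| parameter | default | rationale |
| --- | --- | --- |
| first-start hazard | 21→22.5 (2002) →16.5 (2005) →17.9 /1000 PY | stable-to-declining new-user rate with a mid-2000s dip |
| restart multiplier | 2.0 | prior users restart more readily than never-users start |
| class mix (SSRI/TCA/other) | 0.34/0.59/0.07 → 0.56/0.28/0.16 | SSRIs displacing tricyclics over the window |
| female:male start ratio | 2.0 → 1.2 | female excess narrowing over time |
| episode length | log-normal, median 42→60 d by start year, σ = 1.8 | short typical courses with a heavy long-term tail |
| refill cadence | 28 days | standard repeat-prescription interval |
| missing dosing instructions | 20% of scripts | exercises the median-imputation path |
| depression flag | 67% of users, 5% of non-users | a majority, not all, of users carry a depression code |
| low-dose amitriptyline | 40% of TCA scripts | low-dose tricyclic use for pain is common |
| registration | 55% registered at window open; exit hazard 0.06/yr | mixed prevalent/incident registration with turnover |

Registration dates are recorded clipped to the window start (the convention
of an extract whose observation begins there), and exits are memoryless, so
residual stays for already-registered patients are drawn from the window
opening. Starts are drawn from a piecewise-constant calendar-year hazard by
inversion; each episode samples a class, a product (with unit strength and
1–2 units/day), and a log-normal intended duration; repeat scripts are
issued every refill interval with the last script sized to the remaining
days, and episodes are censored at de-registration and the window end.

**Recovery guarantee.** Consecutive latent episodes are separated by
strictly more than 123 days (the longest 4-calendar-month span) plus one
refill interval plus a margin, so stitched episodes equal latent episodes
in number by construction, and exactly in duration when dosing instructions
are complete. With missing instructions, imputation of a partial final
script can lengthen an episode by at most one refill interval minus a day —
enough to preserve counts, not exact durations; the exact-recovery
experiment therefore runs with complete instructions.

**What the generator does not emulate.** No co-prescribing or mid-episode
switching (one product per latent episode — stitching across products is
tested with constructed streams instead); no dose titration; no
practice-level clustering; no accumulated stock of patients already on
long-term treatment when the window opens. The last point means the default
cohort's prevalence series is flatter than real prescribing series, which
inherit decades of accumulated long-term users; the mechanism experiment
below creates that accumulation explicitly. Passing tests on this generator
therefore establish the correctness of the accounting and estimation
machinery, not the realism of any particular empirical series.

## Verification experiments and problem sizes

The acceptance tests and `scripts/acceptance.py` run four experiments,
sized to finish comfortably on one CPU:

1. **Person-time worked example** — a single patient, exact to day
   quantisation.
2. **Episode oracle** — 1000 random streams of 1–8 scripts vs the
   union-find merge oracle; agreement must be exact.
3. **Truth recovery** — 10,000 patients, constant 20/1000 PY hazard,
   complete instructions: latent episodes recovered exactly; yearly
   incidence on naive person-time within 3 Poisson SDs of 20. The check
   involves 17 yearly comparisons, so the maximum |z| occasionally brushes
   3 by chance at some seeds; the weighted mean rate sits within a fraction
   of a unit of 20.
4. **Mechanism reproduction** — 20,000 patients, flat hazard, no restarts,
   episode-length medians growing geometrically (30 d × 1.22^(year−1992)):
   incidence flat (selected segments within a ±2.5% APC noise band),
   prevalence rising monotonically in 3-year block means with all selected
   APCs positive, and the >365-day share of incident episodes rising while
   the ≤30-day share falls. Yearly prevalence increments at this size are
   comparable to Monte-Carlo noise, which is why monotonicity is asserted
   on block means and the fitted trend rather than on raw year-over-year
   differences.
5. **Segmented-trend recovery** — noiseless two-segment series (2%→8% APC,
   break 2005) recovered exactly; across 200 replicates with 2% log-scale
   noise the modal selected break falls within one year of the truth.

## Known limitations

* Prevalence counts issue-years, so an unusually long gap *within* an
  episode (possible only below the stitching threshold) can skip a
  calendar year; with a 28-day cadence this does not occur.
* The joinpoint fit assumes homoscedastic log-rate errors; no
  autocorrelation adjustment or joinpoint confidence intervals.
* The low-dose amitriptyline sensitivity defaults to prescription-level
  exclusion; patient-level exclusion (dropping patients whose every script
  is flagged) is available but also removes their non-TCA exposure.
* The depression subgroup is a per-patient boolean; no code-list logic.
* Validation reports problems and refuses to repair; records with
  unparseable dates must be fixed upstream.
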