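# Methods

## The audit procedure

A cohort is three tables: `persons` (demographics, self-reported race and
ethnicity, vital status, an address-present flag), `events` (diagnosis,
medication and outpatient-visit records), and `observation_periods`
(start/end intervals of health-system contact), plus a `reference_date` — the
"time of the query" against which vital status is judged. Race comes from a
closed eight-category US-style vocabulary, ethnicity from a three-category
one; anything unrecognized maps to Unknown, because unknownness is part of the
phenomenon being audited, not an error. UK-convention single-field labels are
harmonized onto the race vocabulary (Caribbean/African/Black British → Black
or African; Bangladeshi/Chinese/Indian/Pakistani/… → Asian;
British/Irish/white → White; mixed combinations → Mixed; don't-know/prefer-not
→ Unknown; other ethnic group → Other), with ethnicity set to Unknown since
the UK convention carries no separate ethnicity axis.

Nineteen completeness filters are applied **independently** — each against the
full baseline cohort, never chained — in three categories:

* **Demographics (9):** alive at query time; age and sex both recorded; six
  age-at-diagnosis filters (≥18, ≤21, ≤40, ≤65, ≥65, ≤80); address or zip
  recorded.
* **Medical interactions (3):** at least one diagnosis / medication /
  outpatient visit.
* **Observation period (7):** a recorded period spanning at least 1 week,
  2 weeks, 1 month, 6 months, 1, 2, or 6 years.

For every filter, remaining counts are tabulated per race group, per ethnicity
group, and for the *all* group (every patient, Unknown and Other included);
availability is 100·remaining/baseline rounded to two decimals. Race-group
counts sum to the all-group count by construction (ditto ethnicity), a checked
invariant. Drop-off curves order the filters by descending all-group
availability (catalogue order breaks ties); the points are not cumulative.

## The bias test

For group g versus baseline b (White for race, non-Hispanic or non-Latino for
ethnicity — both overridable), with pre-filter sizes n_g, n_b and survivors
k_g, k_b, the test compares

    observed = k_g / (k_g + k_b)    against    expected = n_g / (n_g + n_b).

Under equal removal rates, conditioning on the combined survivor count,
k_g ~ Binomial(k_g + k_b, expected). The default one-sided lower tail
P(X ≤ k_g) tests under-representation among survivors; a two-sided variant is
available. The Bonferroni family is all applicable tests emitted for the run
(both groupings × all filters); rows with zero combined survivors are recorded
as not-applicable and excluded from the family. Significance is p_adj < α,
default α = 0.05.

## Numerical and semantic choices

* **Exact binomial tails.** The lower tail is the exact CDF up to 10⁷ trials
  (scipy's regularized incomplete beta, numerically stable at millions of
  trials); beyond that a normal approximation with continuity correction takes
  over. The test suite checks the exact path against an independent oracle
  that enumerates the PMF in exact integer arithmetic over the float's dyadic
  representation; agreement is at the 10⁻¹⁴ level.
* **Age** is calendar age: completed years at the event date (year difference,
  minus one before the birthday anniversary; Feb-29 birthdays count from
  Mar 1 in non-leap years). The common floor((event−birth)/365.25) shortcut
  was rejected because it returns 64 on a patient's exact 65th birthday
  (65 years spanning 16 leap days is 23,741 days; /365.25 = 64.9993), which
  contradicts the intended inclusive boundary semantics — a patient diagnosed
  at exactly 65 must pass both the ≤65 and the ≥65 filter. All age bounds are
  inclusive.
* **Alive** means no recorded death, or death strictly after the reference
  date: a death recorded on the query date counts as deceased.
* **Observation spans** are end − start in whole days (a 7-day filter needs
  end ≥ start + 7 days), with calendar labels fixed as 7/14/30/182/365/730/2190
  days so the predicate is locale-independent. With multiple periods per
  patient the longest single period is tested by default (`obs_rule="longest"`),
  since the requirement is *a* recorded observation period; summing is
  available as `"summed"`.
* **Missing birth dates** exclude a patient from every age filter rather than
  raising: differential missingness is exactly what the audit measures.
* **Percentages** round half-away-from-zero at two decimals, computed in exact
  decimal arithmetic, matching how cohort-composition tables are printed.
* Groups absent from a cohort are omitted from the availability table, not
  zero-filled.

## The synthetic-cohort generator

The generator emulates the structural features the filters are sensitive to,
nothing more. Per patient: race and ethnicity are independent multinomial
draws (defaults: the composition of a ~4-million-patient academic medical
center — White 49.42%, Unknown 35.89%, Black or African 9.26%, Asian 5.11%,
Native Hawaiian or Pacific Islander 0.18%, American Indian and/or Alaska
Native 0.14%; ethnicity 8.55% Hispanic / 41.97% non-Hispanic / 49.48%
Unknown). Each of seven data elements (sex, birth date, address, diagnosis,
medication, outpatient visit, observation period) is present with a baseline
probability (defaults 0.95, 0.95, 0.85, 0.85, 0.70, 0.75, 0.70 — chosen as
plausible single-site EHR completeness levels where roughly a quarter to a
third of patients fail any one record-based filter). Planted bias shifts an
element's presence probability on the log-odds scale per group,
p = expit(logit(base) + log(multiplier)), which stays in (0,1) for any
baseline; a multiplier of 1 is the exact null.

Ages at the reference date are truncated-normal ≥ 0 (mean 45, sd 20 years, a
generic adult-medicine case mix); birth dates derive from age. A death is
recorded with probability 0.05 (multiplier element `death`), dated uniformly
within 10 years before the reference date and clipped to follow birth. Event
counts per kind are zero-truncated Poisson (mean 3) given element presence,
dated uniformly over the patient's lifetime within the 10-year lookback.
Observation-period spans are log-normal (median 500 days, log-sd 1.2, capped
at 100 years), ending 0–364 days before the reference date; the log-normal
spread produces the graded attrition across the 1-week…6-year filters that
real attrition tables show. A `stratified_exact` mode draws group sizes by
largest-remainder rounding so configured marginals are hit exactly.

All draws come from one seeded stream (sub-streams per table spawned in fixed
order), so a fixed config is bytewise reproducible end to end — the written
CSVs sort rows and columns canonically and the run manifest carries the config
hash and seed but no timestamp.

Because presence is independent across elements and patients given group, the
filter→element dependency map (alive→death; age filters→birth date +
diagnosis; age/sex→birth date + sex; record filters→their element;
observation filters→period presence and duration) yields the exact set of
(group, filter) pairs whose survival differs from baseline: the planted
ground truth used in recovery tests.

**What the generator does not emulate:** coded vocabularies, disease
trajectories, visit-type ontologies, within-patient longitudinal correlation,
or correlation between elements beyond shared group membership. Passing the
recovery and calibration checks therefore demonstrates that the *pipeline*
detects differential availability of the planted form at the stated effect
size and sample size — not that any particular real dataset is or is not
biased, and not robustness to correlated-missingness mechanisms real EHRs may
exhibit.

## Problem sizes and calibration results

The calibration studies use cohort sizes at which the checks are sharp yet
cheap: type-I error uses 200 null replicates of 15,000 patients (5,000 per
race group, ~57 tests per replicate) and checks the pooled post-Bonferroni
significant fraction against 0.05 within three binomial standard errors;
recovery plants log-odds −0.7 on one group's medication and
observation-period elements in 50 replicates of 20,000 patients (10,000 per
group) and requires pooled sensitivity and specificity ≥ 0.95. The additivity
sweep uses 200 cohorts of 1,000 patients. These are the same quantities
`scripts/acceptance.py` recomputes.

## Known limitations

* The binomial test conditions on the combined survivor count and treats the
  expected share as fixed; like the underlying procedure it ignores sampling
  variability in the baseline group's survival, which is negligible at EHR
  scale but anticonservative for very small groups.
* The choice of baseline group is a modeling decision; the ethnicity baseline
  (non-Hispanic or non-Latino) is configurable precisely because conventions
  differ across studies.
* With one-sided testing, a group *over*-represented after filtering is never
  flagged; use `alternative="two_sided"` to detect deviation in either
  direction.
* The six-year observation filter has few survivors in modest cohorts; its
  per-pair power is the binding constraint on recovery sensitivity (see the
  worked example in the README).
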