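"""The 19 data-completeness filters, as pure predicates over a Cohort.

Each filter answers, for every patient independently, "does this record meet
the completeness requirement?" and returns the surviving patient-id set.
Filters never chain: the audit applies each one to the full baseline cohort.

Conventions (the source descriptions leave these open; all are deterministic):

* Age at an event is calendar age: completed years at the event date
  (the year difference, minus one if the birthday anniversary has not yet
  passed). All age bounds are inclusive, so a patient diagnosed on their
  65th birthday passes both the ``≤65`` and ``≥65`` filters.
* "Alive at the time of the query" requires death_date strictly after the
  cohort's reference_date (a death recorded on the query date counts as
  deceased); a missing death_date counts as alive.
* Observation-period span is ``end_date - start_date`` in whole days; the
  catalogue spans are 7 / 14 / 30 / 182 / 365 / 730 / 2190 days. When a
  patient has several periods the longest single period is tested by default
  (``obs_rule="longest"``); ``"summed"`` adds the spans instead.
* A missing birth_date excludes a patient from every age filter (missingness
  is the phenomenon under audit, not an error).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .datamodel import Cohort, EVENT_KINDS

CATEGORY_DEMOGRAPHICS = "demographics"
CATEGORY_MEDICAL = "medical_interactions"
CATEGORY_OBSERVATION = "observation_period"

#: day counts for the calendar-labelled observation spans
OBS_SPANS: dict[str, int] = {
    "obs_1w": 7,
    "obs_2w": 14,
    "obs_1m": 30,
    "obs_6m": 182,
    "obs_1y": 365,
    "obs_2y": 730,
    "obs_6y": 2190,
}


@dataclass(frozen=True)
class FilterSpec:
    """A named, parameterized completeness predicate from the catalogue."""

    filter_id: str
    category: str
    params: Mapping[str, object] = field(default_factory=dict)
    label: str = ""


def catalogue() -> list[FilterSpec]:
    """The ordered 19-filter catalogue: 9 demographics, 3 medical-interaction,
    7 observation-period filters."""
    specs = [
        FilterSpec("alive", CATEGORY_DEMOGRAPHICS, {}, "Alive"),
        FilterSpec("age_sex", CATEGORY_DEMOGRAPHICS, {}, "AgeSex"),
        FilterSpec("age_ge_18", CATEGORY_DEMOGRAPHICS, {"bound": 18, "direction": "at_least"}, "Age filter >=18"),
        FilterSpec("age_le_21", CATEGORY_DEMOGRAPHICS, {"bound": 21, "direction": "at_most"}, "Age filter <=21"),
        FilterSpec("age_le_40", CATEGORY_DEMOGRAPHICS, {"bound": 40, "direction": "at_most"}, "Age filter <=40"),
        FilterSpec("age_le_65", CATEGORY_DEMOGRAPHICS, {"bound": 65, "direction": "at_most"}, "Age filter <=65"),
        FilterSpec("age_ge_65", CATEGORY_DEMOGRAPHICS, {"bound": 65, "direction": "at_least"}, "Age filter >=65"),
        FilterSpec("age_le_80", CATEGORY_DEMOGRAPHICS, {"bound": 80, "direction": "at_most"}, "Age filter <=80"),
        FilterSpec("has_address", CATEGORY_DEMOGRAPHICS, {}, "Address or zip code"),
        FilterSpec("has_diagnosis", CATEGORY_MEDICAL, {"kind": "diagnosis"}, "Diagnosis"),
        FilterSpec("has_medication", CATEGORY_MEDICAL, {"kind": "medication"}, "Medication"),
        FilterSpec("has_outpatient_visit", CATEGORY_MEDICAL, {"kind": "outpatient_visit"}, "Outpatient visit"),
    ]
    labels = {"obs_1w": "1 week", "obs_2w": "2 weeks", "obs_1m": "1 month",
              "obs_6m": "6 months", "obs_1y": "1 year", "obs_2y": "2 years", "obs_6y": "6 years"}
    for fid, days in OBS_SPANS.items():
        specs.append(FilterSpec(fid, CATEGORY_OBSERVATION, {"min_days": days}, labels[fid]))
    return specs


def calendar_age(birth: "pd.Series", event: "pd.Series") -> np.ndarray:
    """Completed calendar years between birth and event (vectorized).

    A Feb-29 birthday counts from Mar 1 in non-leap years.
    """
    before_anniversary = (event.dt.month * 100 + event.dt.day) < (
        birth.dt.month * 100 + birth.dt.day
    )
    return (event.dt.year - birth.dt.year - before_anniversary).to_numpy()


def filter_alive(cohort: Cohort) -> set:
    """Patients with no recorded death, or a death strictly after reference_date."""
    persons = cohort.persons
    alive = persons["death_date"].isna() | (persons["death_date"] > cohort.reference_date)
    return set(persons.loc[alive, "person_id"])


def filter_age_sex(cohort: Cohort) -> set:
    """Patients with both birth_date and sex recorded."""
    persons = cohort.persons
    ok = persons["birth_date"].notna() & persons["sex"].notna()
    return set(persons.loc[ok, "person_id"])


def filter_has_address(cohort: Cohort) -> set:
    """Patients with an address (or zip / state of residence) recorded."""
    persons = cohort.persons
    return set(persons.loc[persons["address_present"], "person_id"])


def filter_has_event(cohort: Cohort, kind: str) -> set:
    """Patients with at least one event of the given kind recorded."""
    if kind not in EVENT_KINDS:
        raise ValueError(f"unknown event kind {kind!r}; expected one of {EVENT_KINDS}")
    events = cohort.events
    return set(events.loc[events["event_kind"] == kind, "person_id"])


def filter_age_at_diagnosis(cohort: Cohort, bound: int, direction: str) -> set:
    """Patients with ≥1 diagnosis at an age satisfying the inclusive bound.

    Patients with no diagnoses or no birth_date never survive.
    """
    if direction not in ("at_least", "at_most"):
        raise ValueError(f"direction must be 'at_least' or 'at_most', got {direction!r}")
    events = cohort.events
    diag = events[events["event_kind"] == "diagnosis"]
    if diag.empty:
        return set()
    merged = diag.merge(
        cohort.persons[["person_id", "birth_date"]], on="person_id", how="left"
    )
    merged = merged[merged["birth_date"].notna()]
    if merged.empty:
        return set()
    age = calendar_age(merged["birth_date"], merged["event_date"])
    ok = age >= bound if direction == "at_least" else age <= bound
    return set(merged["person_id"].to_numpy()[ok])


def filter_observation_period(cohort: Cohort, min_days: int, obs_rule: str = "longest") -> set:
    """Patients whose observation period spans at least ``min_days`` days.

    Span is end − start in days. Under ``obs_rule="longest"`` the longest
    single period is tested; under ``"summed"`` spans are added per patient.
    Patients with no observation-period record never survive.
    """
    if min_days <= 0:
        raise ValueError(f"min_days must be positive, got {min_days}")
    if obs_rule not in ("longest", "summed"):
        raise ValueError(f"obs_rule must be 'longest' or 'summed', got {obs_rule!r}")
    obs = cohort.observation_periods
    if obs.empty:
        return set()
    spans = (obs["end_date"] - obs["start_date"]).dt.days
    per_patient = spans.groupby(obs["person_id"])
    agg = per_patient.max() if obs_rule == "longest" else per_patient.sum()
    return set(agg.index[agg >= min_days])


def apply_filter(cohort: Cohort, spec: FilterSpec | str, obs_rule: str = "longest") -> set:
    """Evaluate one catalogue filter (by spec or id) against the full cohort."""
    if isinstance(spec, str):
        by_id = {s.filter_id: s for s in catalogue()}
        if spec not in by_id:
            raise ValueError(f"unknown filter_id {spec!r}")
        spec = by_id[spec]
    if spec.filter_id == "alive":
        return filter_alive(cohort)
    if spec.filter_id == "age_sex":
        return filter_age_sex(cohort)
    if spec.filter_id == "has_address":
        return filter_has_address(cohort)
    if spec.category == CATEGORY_MEDICAL:
        return filter_has_event(cohort, str(spec.params["kind"]))
    if spec.category == CATEGORY_OBSERVATION:
        return filter_observation_period(cohort, int(spec.params["min_days"]), obs_rule)
    if spec.filter_id.startswith("age_"):
        return filter_age_at_diagnosis(cohort, int(spec.params["bound"]), str(spec.params["direction"]))
    raise ValueError(f"unknown filter_id {spec.filter_id!r}")
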