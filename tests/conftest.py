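"""Shared fixtures: hand-built toy cohorts with explicit dtypes."""

from __future__ import annotations

import pandas as pd
import pytest

from cohortbias.datamodel import Cohort, validate_cohort


def make_cohort(persons_rows, events_rows=(), obs_rows=(), reference_date="2024-01-01",
                validate=True) -> Cohort:
    """Build a Cohort from plain tuples.

    persons_rows: (person_id, birth_date|None, sex|None, race, ethnicity,
                   death_date|None, address_present)
    events_rows:  (person_id, event_date, event_kind)
    obs_rows:     (person_id, start_date, end_date)
    """
    persons = pd.DataFrame(
        persons_rows,
        columns=["person_id", "birth_date", "sex", "race", "ethnicity",
                 "death_date", "address_present"],
    )
    persons["birth_date"] = pd.to_datetime(persons["birth_date"])
    persons["death_date"] = pd.to_datetime(persons["death_date"])
    persons["address_present"] = persons["address_present"].astype(bool)
    persons["sex"] = persons["sex"].where(persons["sex"].notna())  # None -> NaN

    events = pd.DataFrame(list(events_rows), columns=["person_id", "event_date", "event_kind"])
    events["event_date"] = pd.to_datetime(events["event_date"])
    obs = pd.DataFrame(list(obs_rows), columns=["person_id", "start_date", "end_date"])
    obs["start_date"] = pd.to_datetime(obs["start_date"])
    obs["end_date"] = pd.to_datetime(obs["end_date"])

    cohort = Cohort(persons=persons, events=events, observation_periods=obs,
                    reference_date=pd.Timestamp(reference_date))
    if validate:
        validate_cohort(cohort)
    return cohort


@pytest.fixture
def toy_cohort() -> Cohort:
    """Five patients covering the main filter branches."""
    return make_cohort(
        persons_rows=[
            # alive, complete record
            ("P01", "1980-05-01", "F", "White", "Non-Hispanic or non-Latino", None, True),
            # died on the reference date
            ("P02", "1950-01-01", "M", "Black or African", "Hispanic or Latino", "2024-01-01", True),
            # missing sex and birth date, no address
            ("P03", None, None, "Asian", "Unknown", None, False),
            # alive, no events at all
            ("P04", "2000-01-01", "F", "White", "Non-Hispanic or non-Latino", None, True),
            # death after the reference date
            ("P05", "1970-07-07", "M", "Unknown", "Unknown", "2024-06-01", False),
        ],
        events_rows=[
            ("P01", "1998-06-01", "diagnosis"),
            ("P01", "2020-01-01", "medication"),
            ("P02", "2015-01-01", "diagnosis"),
            ("P02", "2015-01-02", "outpatient_visit"),
            ("P03", "2023-01-01", "diagnosis"),
            ("P05", "2010-01-01", "medication"),
        ],
        obs_rows=[
            ("P01", "2020-01-01", "2020-01-08"),   # exactly 7 days
            ("P02", "2010-01-01", "2016-01-01"),   # ~6 years
            ("P05", "2023-12-01", "2023-12-04"),   # 3 days
        ],
    )
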