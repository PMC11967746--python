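"""Tabular EHR schema: loading, validation, writing, and race/ethnicity harmonization.

The cohort model is a deliberately minimal OMOP-flavoured extract: a person
table (demographics, vital status, address flag), a single long event table
(diagnoses, medications, outpatient visits), and an observation-period table.
Race and ethnicity are separate self-reported fields drawn from closed US-style
vocabularies; UK-convention single-field labels can be harmonized onto the race
vocabulary at load time.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger("cohortbias")

# ---------------------------------------------------------------------------
# Vocabularies
# ---------------------------------------------------------------------------

RACE_CATEGORIES: tuple[str, ...] = (
    "American Indian and/or Alaska Native",
    "Asian",
    "Black or African",
    "Native Hawaiian or Pacific Islander",
    "White",
    "Mixed",
    "Other",
    "Unknown",
)

ETHNICITY_CATEGORIES: tuple[str, ...] = (
    "Hispanic or Latino",
    "Non-Hispanic or non-Latino",
    "Unknown",
)

UNKNOWN = "Unknown"

EVENT_KINDS: tuple[str, ...] = ("diagnosis", "medication", "outpatient_visit")

PERSON_COLUMNS = (
    "person_id",
    "birth_date",
    "sex",
    "race",
    "ethnicity",
    "death_date",
    "address_present",
)
EVENT_COLUMNS = ("person_id", "event_date", "event_kind")
OBS_COLUMNS = ("person_id", "start_date", "end_date")

DEFAULT_NA_STRINGS = ("", "NA", "NaN", "null", "None")


class SchemaError(ValueError):
    """A required column is missing or a value violates the schema."""


class IntegrityError(ValueError):
    """Referential or uniqueness constraints are violated."""


# ---------------------------------------------------------------------------
# UK Biobank race harmonization
# ---------------------------------------------------------------------------

# UK single-field ethnic-group labels mapped onto the US-style race vocabulary
# following the UK government's recommended grouping of the census categories.
_UKBB_RACE_MAP: dict[str, str] = {
    # Black or African origin
    "any other black background": "Black or African",
    "african": "Black or African",
    "black or black british": "Black or African",
    "caribbean": "Black or African",
    # Asian
    "any other asian background": "Asian",
    "asian or asian british": "Asian",
    "bangladeshi": "Asian",
    "chinese": "Asian",
    "indian": "Asian",
    "pakistani": "Asian",
    # White
    "any other white background": "White",
    "british": "White",
    "irish": "White",
    "white": "White",
    # Unknown
    "do not know": "Unknown",
    "prefer not to answer": "Unknown",
    # Mixed
    "any other mixed background": "Mixed",
    "mixed": "Mixed",
    "white and asian": "Mixed",
    "white and black african": "Mixed",
    "white and black caribbean": "Mixed",
    # Other
    "other ethnic group": "Other",
}


def harmonize_ukbb_race(raw_label: object) -> str:
    """Map a UK-convention ethnic-group label onto the US-style race vocabulary.

    Total function: case- and whitespace-insensitive; anything unrecognized
    (including missing values) maps to ``Unknown`` with a warning.
    """
    if raw_label is None or (isinstance(raw_label, float) and pd.isna(raw_label)):
        return UNKNOWN
    key = re.sub(r"\s+", " ", str(raw_label)).strip().lower()
    if key in _UKBB_RACE_MAP:
        return _UKBB_RACE_MAP[key]
    # idempotence: outputs of the mapping are accepted as-is
    for cat in RACE_CATEGORIES:
        if key == cat.lower():
            return cat
    logger.warning("unrecognized UK race label %r mapped to Unknown", raw_label)
    return UNKNOWN


# ---------------------------------------------------------------------------
# Cohort container
# ---------------------------------------------------------------------------


@dataclass
class CohortReadConfig:
    """Options controlling :func:`load_cohort`."""

    reference_date: pd.Timestamp | str | None = None
    na_strings: tuple[str, ...] = DEFAULT_NA_STRINGS
    ukbb_mode: bool = False  # apply harmonize_ukbb_race to the race column


@dataclass
class Cohort:
    """A validated patient cohort: persons, events, observation periods.

    ``reference_date`` is the "time of the query" against which vital status
    is judged; it defaults to the latest event or observation-period date.
    """

    persons: pd.DataFrame
    events: pd.DataFrame
    observation_periods: pd.DataFrame
    reference_date: pd.Timestamp

    @property
    def person_ids(self) -> set:
        return set(self.persons["person_id"])

    def __len__(self) -> int:
        return len(self.persons)


def _normalize_category(value: object, vocabulary: Iterable[str]) -> str:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return UNKNOWN
    text = re.sub(r"\s+", " ", str(value)).strip()
    for cat in vocabulary:
        if text.lower() == cat.lower():
            return cat
    return ""  # sentinel: unrecognized


def _require_columns(df: pd.DataFrame, required: tuple[str, ...], table: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{table} table is missing required column(s): {', '.join(missing)}")


def _parse_dates(series: pd.Series, column: str) -> pd.Series:
    parsed = pd.to_datetime(series, format="%Y-%m-%d", errors="coerce")
    bad = series.notna() & (series.astype(str).str.strip() != "") & parsed.isna()
    if bad.any():
        offenders = series[bad].unique()[:5]
        raise SchemaError(f"column {column}: unparseable ISO-8601 dates, e.g. {list(offenders)}")
    return parsed


def _parse_bool(series: pd.Series) -> pd.Series:
    mapping = {"true": True, "false": False, "1": True, "0": False, "True": True, "False": False}
    out = series.astype(str).str.strip().map(mapping)
    out[series.isna()] = False
    if out.isna().any():
        bad = series[out.isna()].unique()[:5]
        raise SchemaError(f"column address_present: expected true/false, got {list(bad)}")
    return out.astype(bool)


def validate_cohort(cohort: Cohort) -> None:
    """Raise SchemaError / IntegrityError if any cohort invariant is violated."""
    persons, events, obs = cohort.persons, cohort.events, cohort.observation_periods
    _require_columns(persons, PERSON_COLUMNS, "persons")
    _require_columns(events, EVENT_COLUMNS, "events")
    _require_columns(obs, OBS_COLUMNS, "observation_periods")

    dup = persons["person_id"][persons["person_id"].duplicated()]
    if len(dup):
        raise IntegrityError(f"duplicate person_id(s): {sorted(set(dup))[:10]}")

    known = set(persons["person_id"])
    for name, frame in (("events", events), ("observation_periods", obs)):
        dangling = sorted(set(frame["person_id"]) - known)
        if dangling:
            raise IntegrityError(f"{name} table references unknown person_id(s): {dangling[:10]}")

    bad_race = set(persons["race"]) - set(RACE_CATEGORIES)
    if bad_race:
        raise SchemaError(f"race values outside vocabulary: {sorted(bad_race)[:10]}")
    bad_eth = set(persons["ethnicity"]) - set(ETHNICITY_CATEGORIES)
    if bad_eth:
        raise SchemaError(f"ethnicity values outside vocabulary: {sorted(bad_eth)[:10]}")

    both = persons["birth_date"].notna() & persons["death_date"].notna()
    if (persons.loc[both, "death_date"] < persons.loc[both, "birth_date"]).any():
        raise IntegrityError("death_date earlier than birth_date for at least one patient")

    if len(events) and events["event_date"].isna().any():
        raise SchemaError("events table contains missing event_date")
    bad_kind = set(events["event_kind"]) - set(EVENT_KINDS)
    if bad_kind:
        raise SchemaError(f"unknown event_kind value(s): {sorted(bad_kind)}")

    if len(obs) and (obs["end_date"] < obs["start_date"]).any():
        raise IntegrityError("observation period with end_date before start_date")


def load_cohort(
    person_path: str | Path,
    events_path: str | Path,
    obs_path: str | Path,
    config: CohortReadConfig | None = None,
) -> Cohort:
    """Read the three CSV tables, validate them, and assemble a Cohort.

    Unrecognized race/ethnicity strings are mapped to ``Unknown`` (the count is
    logged); in ``ukbb_mode`` the race column is first passed through
    :func:`harmonize_ukbb_race` and ethnicity is forced to ``Unknown``.
    """
    config = config or CohortReadConfig()
    for path in (person_path, events_path, obs_path):
        if not Path(path).exists():
            raise FileNotFoundError(f"input file not found: {path}")

    na = list(config.na_strings)
    persons = pd.read_csv(person_path, dtype=str, na_values=na, keep_default_na=False)
    events = pd.read_csv(events_path, dtype=str, na_values=na, keep_default_na=False)
    obs = pd.read_csv(obs_path, dtype=str, na_values=na, keep_default_na=False)

    _require_columns(persons, PERSON_COLUMNS, "persons")
    _require_columns(events, EVENT_COLUMNS, "events")
    _require_columns(obs, OBS_COLUMNS, "observation_periods")

    persons = persons.copy()
    persons["birth_date"] = _parse_dates(persons["birth_date"], "birth_date")
    persons["death_date"] = _parse_dates(persons["death_date"], "death_date")
    persons["address_present"] = _parse_bool(persons["address_present"])
    persons["sex"] = persons["sex"].where(persons["sex"].notna() & (persons["sex"].str.strip() != ""))

    if config.ukbb_mode:
        persons["race"] = persons["race"].map(harmonize_ukbb_race)
        persons["ethnicity"] = UNKNOWN
    else:
        for col, vocab in (("race", RACE_CATEGORIES), ("ethnicity", ETHNICITY_CATEGORIES)):
            normalized = persons[col].map(lambda v: _normalize_category(v, vocab))
            n_unknown = int((normalized == "").sum())
            if n_unknown:
                logger.info("%d unrecognized %s value(s) mapped to Unknown", n_unknown, col)
            persons[col] = normalized.replace("", UNKNOWN)

    events = events.copy()
    events["event_date"] = _parse_dates(events["event_date"], "event_date")
    obs = obs.copy()
    obs["start_date"] = _parse_dates(obs["start_date"], "start_date")
    obs["end_date"] = _parse_dates(obs["end_date"], "end_date")

    if config.reference_date is not None:
        reference_date = pd.Timestamp(config.reference_date)
    else:
        candidates = [events["event_date"].max(), obs["end_date"].max(), persons["death_date"].max()]
        candidates = [c for c in candidates if pd.notna(c)]
        reference_date = max(candidates) if candidates else pd.Timestamp.today().normalize()

    cohort = Cohort(
        persons=persons.sort_values("person_id", kind="mergesort").reset_index(drop=True),
        events=events.sort_values(["person_id", "event_date", "event_kind"], kind="mergesort").reset_index(drop=True),
        observation_periods=obs.sort_values(["person_id", "start_date", "end_date"], kind="mergesort").reset_index(drop=True),
        reference_date=reference_date,
    )
    validate_cohort(cohort)
    return cohort


def _date_str(series: pd.Series) -> pd.Series:
    out = series.dt.strftime("%Y-%m-%d")
    return out.where(series.notna(), "")


def write_cohort(cohort: Cohort, out_dir: str | Path) -> dict[str, Path]:
    """Write the three tables as CSV so that :func:`load_cohort` round-trips.

    Dates are ISO-8601, booleans ``true``/``false``, rows sorted by person_id
    (then dates), column order fixed — two writes of equal cohorts are
    byte-identical.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    persons = cohort.persons.sort_values("person_id", kind="mergesort").copy()
    persons["birth_date"] = _date_str(persons["birth_date"])
    persons["death_date"] = _date_str(persons["death_date"])
    persons["sex"] = persons["sex"].fillna("")
    persons["address_present"] = persons["address_present"].map({True: "true", False: "false"})

    events = cohort.events.sort_values(["person_id", "event_date", "event_kind"], kind="mergesort").copy()
    events["event_date"] = _date_str(events["event_date"])
    obs = cohort.observation_periods.sort_values(["person_id", "start_date", "end_date"], kind="mergesort").copy()
    obs["start_date"] = _date_str(obs["start_date"])
    obs["end_date"] = _date_str(obs["end_date"])

    paths = {
        "persons": out_dir / "persons.csv",
        "events": out_dir / "events.csv",
        "observation_periods": out_dir / "observation_periods.csv",
    }
    persons[list(PERSON_COLUMNS)].to_csv(paths["persons"], index=False, lineterminator="\n")
    events[list(EVENT_COLUMNS)].to_csv(paths["events"], index=False, lineterminator="\n")
    obs[list(OBS_COLUMNS)].to_csv(paths["observation_periods"], index=False, lineterminator="\n")
    return paths
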