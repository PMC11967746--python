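"""Non-cumulative filter audit: per-group data availability against the full cohort.

Every filter is applied one at a time to the complete baseline cohort — never
to another filter's output — and the surviving counts are tabulated per race
group, per ethnicity group, and for the ``all`` group (every patient in the
cohort, Unknown and Other included). Availability is the percentage of a
group's baseline patients that survive a filter.
"""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Sequence

import pandas as pd

from .datamodel import Cohort
from .filters import FilterSpec, apply_filter, catalogue

GROUPING_ALL = "all"
GROUPING_RACE = "race"
GROUPING_ETHNICITY = "ethnicity"

AVAILABILITY_COLUMNS = ("grouping", "group", "filter_id", "baseline_n", "remaining_n", "remaining_pct")


def percent_remaining(remaining_n: int, baseline_n: int) -> float:
    """100·remaining/baseline, rounded to 2 decimals half-away-from-zero.

    This is the print convention of the availability tables; rounding is done
    in exact decimal arithmetic so e.g. (1992336, 4031307) → 49.42.
    """
    if baseline_n == 0:
        raise ZeroDivisionError("baseline_n must be positive")
    if not 0 <= remaining_n <= baseline_n:
        raise ValueError(f"remaining_n={remaining_n} outside [0, baseline_n={baseline_n}]")
    exact = Decimal(remaining_n * 100) / Decimal(baseline_n)
    return float(exact.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def run_audit(
    cohort: Cohort,
    specs: Sequence[FilterSpec] | None = None,
    obs_rule: str = "longest",
) -> pd.DataFrame:
    """Apply each filter independently and tabulate remaining counts per group.

    Returns a long-format frame with one row per (grouping, group, filter):
    ``grouping`` ∈ {all, race, ethnicity}; groups with zero baseline patients
    are omitted rather than zero-filled. Race-group remaining counts sum to
    the all-group count for every filter (ditto ethnicity).
    """
    if specs is None:
        specs = catalogue()
    if not specs:
        raise ValueError("spec list must be non-empty")

    persons = cohort.persons
    groupings: list[tuple[str, pd.Series]] = [
        (GROUPING_ALL, pd.Series(GROUPING_ALL, index=persons.index)),
        (GROUPING_RACE, persons["race"]),
        (GROUPING_ETHNICITY, persons["ethnicity"]),
    ]

    rows = []
    for spec in specs:
        survivors = apply_filter(cohort, spec, obs_rule=obs_rule)
        survived = persons["person_id"].isin(survivors)
        for grouping, labels in groupings:
            baseline = labels.value_counts()
            remaining = labels[survived].value_counts()
            for group, baseline_n in baseline.items():
                remaining_n = int(remaining.get(group, 0))
                rows.append((grouping, group, spec.filter_id, int(baseline_n),
                             remaining_n, percent_remaining(remaining_n, int(baseline_n))))

    table = pd.DataFrame(rows, columns=list(AVAILABILITY_COLUMNS))
    order = {s.filter_id: i for i, s in enumerate(specs)}
    table = table.sort_values(
        ["grouping", "group", "filter_id"],
        key=lambda col: col.map(order) if col.name == "filter_id" else col,
        kind="mergesort",
    ).reset_index(drop=True)
    return table


def to_wide(table: pd.DataFrame) -> pd.DataFrame:
    """Reshape the long availability table into a filters × groups percentage grid."""
    wide = table.pivot_table(
        index="filter_id",
        columns=["grouping", "group"],
        values="remaining_pct",
        sort=False,
        aggfunc="first",
    )
    cat_order = [s.filter_id for s in catalogue()]
    seen = [f for f in cat_order if f in wide.index] + [f for f in wide.index if f not in cat_order]
    return wide.loc[seen]


def cohort_summary(cohort: Cohort) -> dict:
    """JSON-ready cohort metadata: sizes and group marginals."""
    persons = cohort.persons
    return {
        "n_patients": int(len(persons)),
        "n_events": int(len(cohort.events)),
        "n_observation_periods": int(len(cohort.observation_periods)),
        "reference_date": str(cohort.reference_date.date()),
        "race_counts": {k: int(v) for k, v in persons["race"].value_counts().items()},
        "ethnicity_counts": {k: int(v) for k, v in persons["ethnicity"].value_counts().items()},
    }
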