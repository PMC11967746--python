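"""Seeded synthetic EHR cohorts with group-correlated data availability.

The generator stands in for restricted clinical datasets: patients get a
race and an ethnicity from configurable multinomial marginals (defaults are
the marginals of a large academic-medical-center cohort), and each data
element — sex, birth date, address, diagnosis/medication/visit records,
observation period — is present with a per-element baseline probability.
Group-wise differential availability is *planted* on the log-odds scale:

    P(element present | patient in group g) = expit(logit(base) + log(mult_g))

so a multiplier of 1 is the null and e.g. exp(-0.7) ≈ 0.5 halves the odds of
the element being recorded for that group. Because the filter→element
dependency is known, the set of (group, filter) pairs that should show bias
is recoverable as ground truth (:func:`planted_truth`).

Everything is drawn from a single seeded stream (sub-streams per table are
spawned in fixed order), so a fixed config yields byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import expit, logit

from .datamodel import (
    Cohort,
    ETHNICITY_CATEGORIES,
    RACE_CATEGORIES,
    validate_cohort,
)
from .filters import OBS_SPANS

#: data elements whose presence is Bernoulli per patient
PRESENCE_ELEMENTS = (
    "sex",
    "birth_date",
    "address",
    "diagnosis",
    "medication",
    "outpatient_visit",
    "observation_period",
)

#: extra multiplier keys: "death" scales the odds of a recorded death,
#: "observation_duration" multiplies the observation-period span.
EXTRA_ELEMENTS = ("death", "observation_duration")

#: which data elements each catalogue filter depends on
FILTER_DEPENDENCIES: dict[str, frozenset[str]] = {
    "alive": frozenset({"death"}),
    "age_sex": frozenset({"birth_date", "sex"}),
    "age_ge_18": frozenset({"birth_date", "diagnosis"}),
    "age_le_21": frozenset({"birth_date", "diagnosis"}),
    "age_le_40": frozenset({"birth_date", "diagnosis"}),
    "age_le_65": frozenset({"birth_date", "diagnosis"}),
    "age_ge_65": frozenset({"birth_date", "diagnosis"}),
    "age_le_80": frozenset({"birth_date", "diagnosis"}),
    "has_address": frozenset({"address"}),
    "has_diagnosis": frozenset({"diagnosis"}),
    "has_medication": frozenset({"medication"}),
    "has_outpatient_visit": frozenset({"outpatient_visit"}),
    **{fid: frozenset({"observation_period", "observation_duration"}) for fid in OBS_SPANS},
}

# Default marginals: the race/ethnicity composition of a ~4M-patient academic
# medical center (American Indian and/or Alaska Native 0.14%, Asian 5.11%,
# Black or African 9.26%, Native Hawaiian or Pacific Islander 0.18%,
# White 49.42%, Unknown 35.89%; Hispanic 8.55% / non-Hispanic 41.97% /
# Unknown 49.48%).
DEFAULT_RACE_PROBS: dict[str, float] = {
    "American Indian and/or Alaska Native": 0.0014,
    "Asian": 0.0511,
    "Black or African": 0.0926,
    "Native Hawaiian or Pacific Islander": 0.0018,
    "White": 0.4942,
    "Unknown": 0.3589,
}
DEFAULT_ETHNICITY_PROBS: dict[str, float] = {
    "Hispanic or Latino": 0.0855,
    "Non-Hispanic or non-Latino": 0.4197,
    "Unknown": 0.4948,
}
DEFAULT_PRESENCE_PROBS: dict[str, float] = {
    "sex": 0.95,
    "birth_date": 0.95,
    "address": 0.85,
    "diagnosis": 0.85,
    "medication": 0.70,
    "outpatient_visit": 0.75,
    "observation_period": 0.70,
}

DEFAULT_REFERENCE_DATE = "2024-01-01"
_LOOKBACK_DAYS = 3650  # events and deaths fall within 10 years of the query


class ConfigError(ValueError):
    """Invalid synthetic-cohort configuration."""


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic cohort.

    ``group_multipliers`` maps a race or ethnicity category to per-element odds
    multipliers, e.g. ``{"Black or African": {"medication": 0.5}}`` halves that
    group's odds of having any medication record. ``stratified_exact`` draws
    group sizes by largest-remainder rounding of the marginals instead of
    multinomially, so configured percentages are hit exactly.
    """

    n_patients: int = 10_000
    race_probs: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_RACE_PROBS))
    ethnicity_probs: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_ETHNICITY_PROBS))
    presence_probs: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_PRESENCE_PROBS))
    group_multipliers: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    age_mean: float = 45.0       # years at reference date
    age_sd: float = 20.0
    event_rate: float = 3.0      # mean events per patient per kind, given presence
    obs_log_mean: float = math.log(500.0)   # log-days; median span ~ 500 days
    obs_log_sd: float = 1.2
    death_prob: float = 0.05     # probability of a recorded death before reference
    reference_date: str = DEFAULT_REFERENCE_DATE
    stratified_exact: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name, probs, vocab in (
            ("race_probs", self.race_probs, RACE_CATEGORIES),
            ("ethnicity_probs", self.ethnicity_probs, ETHNICITY_CATEGORIES),
        ):
            unknown = set(probs) - set(vocab)
            if unknown:
                raise ConfigError(f"{name} has unknown categories: {sorted(unknown)}")
            vals = list(probs.values())
            if any(not 0.0 <= v <= 1.0 for v in vals):
                raise ConfigError(f"{name} values must lie in [0, 1]")
            if abs(sum(vals) - 1.0) > 1e-9:
                raise ConfigError(f"{name} must sum to 1 (got {sum(vals)!r})")
        unknown = set(self.presence_probs) - set(PRESENCE_ELEMENTS)
        if unknown:
            raise ConfigError(f"presence_probs has unknown elements: {sorted(unknown)}")
        if any(not 0.0 <= v <= 1.0 for v in self.presence_probs.values()):
            raise ConfigError("presence probabilities must lie in [0, 1]")
        if not 0.0 <= self.death_prob <= 1.0:
            raise ConfigError("death_prob must lie in [0, 1]")
        valid_elements = set(PRESENCE_ELEMENTS) | set(EXTRA_ELEMENTS)
        for group, mults in self.group_multipliers.items():
            if group not in RACE_CATEGORIES and group not in ETHNICITY_CATEGORIES:
                raise ConfigError(f"group_multipliers group {group!r} not a race/ethnicity category")
            bad = set(mults) - valid_elements
            if bad:
                raise ConfigError(f"group_multipliers[{group!r}] has unknown elements: {sorted(bad)}")
            if any(m <= 0 for m in mults.values()):
                raise ConfigError("odds multipliers must be positive")
        if self.n_patients < 0:
            raise ConfigError("n_patients must be non-negative")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: Mapping) -> "SyntheticConfig":
        return cls(**dict(data))


def _largest_remainder_counts(probs: dict[str, float], n: int) -> dict[str, int]:
    """Deterministic integer group sizes summing to n (largest-remainder rule)."""
    cats = list(probs)
    quotas = np.array([probs[c] * n for c in cats])
    floors = np.floor(quotas).astype(int)
    short = n - int(floors.sum())
    # ties broken by category order for determinism
    order = np.argsort(-(quotas - floors), kind="stable")
    for i in order[:short]:
        floors[i] += 1
    return dict(zip(cats, floors.tolist()))


def _draw_labels(rng: np.random.Generator, probs: Mapping[str, float], n: int, exact: bool) -> np.ndarray:
    cats = list(probs)
    if exact:
        counts = _largest_remainder_counts(dict(probs), n)
        labels = np.repeat(cats, [counts[c] for c in cats])
        rng.shuffle(labels)
        return labels
    return rng.choice(cats, size=n, p=[probs[c] for c in cats])


def _element_probability(
    base: float, races: np.ndarray, ethnicities: np.ndarray, element: str,
    multipliers: Mapping[str, Mapping[str, float]],
) -> np.ndarray:
    """Per-patient presence probability on the log-odds scale."""
    if base <= 0.0 or base >= 1.0:
        return np.full(len(races), base)
    shift = np.zeros(len(races))
    for group, mults in multipliers.items():
        if element in mults:
            member = (races == group) | (ethnicities == group)
            shift[member] += math.log(mults[element])
    return expit(logit(base) + shift)


def _zero_truncated_poisson(rng: np.random.Generator, mu: float, size: int) -> np.ndarray:
    """Counts ~ Poisson(mu) conditioned on being >= 1 (inverse-CDF draw)."""
    if size == 0:
        return np.zeros(0, dtype=int)
    p0 = math.exp(-mu)
    u = rng.uniform(p0, 1.0, size=size)
    return sps.poisson.ppf(u, mu).astype(int)


def generate_cohort(config: SyntheticConfig) -> Cohort:
    """Draw a full synthetic cohort (persons, events, observation periods).

    Ages are truncated-normal (≥ 0) at the reference date; birth dates are
    derived from age; deaths, when drawn, fall uniformly within 10 years
    before the reference date; event counts are zero-truncated Poisson per
    kind given presence; observation-period spans are log-normal in days.
    """
    n = config.n_patients
    ref = pd.Timestamp(config.reference_date)
    ss = np.random.SeedSequence(config.seed)
    rng_person, rng_elem, rng_event, rng_obs = (np.random.default_rng(c) for c in ss.spawn(4))

    person_id = np.array([f"P{i:07d}" for i in range(n)])
    races = _draw_labels(rng_person, config.race_probs, n, config.stratified_exact)
    ethnicities = _draw_labels(rng_person, config.ethnicity_probs, n, config.stratified_exact)

    presence: dict[str, np.ndarray] = {}
    for element in PRESENCE_ELEMENTS:
        base = float(config.presence_probs.get(element, DEFAULT_PRESENCE_PROBS[element]))
        p = _element_probability(base, races, ethnicities, element, config.group_multipliers)
        presence[element] = rng_elem.uniform(size=n) < p

    # ages & birth dates (drawn for everyone; masked by the birth_date element)
    if config.age_sd > 0:
        a = (0.0 - config.age_mean) / config.age_sd
        ages = sps.truncnorm.rvs(a, np.inf, loc=config.age_mean, scale=config.age_sd,
                                 size=n, random_state=rng_person)
    else:
        ages = np.full(n, max(config.age_mean, 0.0))
    age_days = np.round(ages * 365.25).astype(int)
    birth = ref - pd.to_timedelta(age_days, unit="D")
    birth_date = pd.Series(birth).where(pd.Series(presence["birth_date"]), pd.NaT)

    sex = pd.Series(np.where(rng_person.uniform(size=n) < 0.5, "F", "M"))
    sex = sex.where(pd.Series(presence["sex"]))

    p_death = _element_probability(config.death_prob, races, ethnicities, "death",
                                   config.group_multipliers)
    dead = rng_person.uniform(size=n) < p_death
    death_offset = rng_person.integers(0, _LOOKBACK_DAYS, size=n)
    death = ref - pd.to_timedelta(death_offset, unit="D")
    # a recorded death never precedes a recorded birth
    death = pd.Series(death)
    has_birth = birth_date.notna()
    death = death.where(~has_birth | (death >= birth_date), birth_date)
    death_date = death.where(pd.Series(dead), pd.NaT)

    persons = pd.DataFrame({
        "person_id": person_id,
        "birth_date": birth_date,
        "sex": sex,
        "race": races,
        "ethnicity": ethnicities,
        "death_date": death_date,
        "address_present": presence["address"],
    })

    # events: per kind, zero-truncated Poisson counts for patients with the
    # element present; event dates uniform over the patient's lifetime within
    # the 10-year lookback window
    event_frames = []
    max_back = np.minimum(age_days, _LOOKBACK_DAYS)
    max_back = np.where(presence["birth_date"], max_back, _LOOKBACK_DAYS)
    max_back = np.maximum(max_back, 1)
    for kind in ("diagnosis", "medication", "outpatient_visit"):
        mask = presence[kind]
        idx = np.flatnonzero(mask)
        counts = _zero_truncated_poisson(rng_event, config.event_rate, len(idx))
        owners = np.repeat(idx, counts)
        offsets = rng_event.integers(0, np.repeat(max_back[idx], counts))
        event_frames.append(pd.DataFrame({
            "person_id": person_id[owners],
            "event_date": ref - pd.to_timedelta(offsets, unit="D"),
            "event_kind": kind,
        }))
    events = (pd.concat(event_frames, ignore_index=True) if event_frames
              else pd.DataFrame(columns=["person_id", "event_date", "event_kind"]))

    # observation periods: one per patient with the element, log-normal span
    obs_idx = np.flatnonzero(presence["observation_period"])
    durations = np.round(np.exp(rng_obs.normal(config.obs_log_mean, config.obs_log_sd,
                                               size=len(obs_idx)))).astype(int)
    dur_scale = np.ones(len(obs_idx))
    for group, mults in config.group_multipliers.items():
        if "observation_duration" in mults:
            member = (races[obs_idx] == group) | (ethnicities[obs_idx] == group)
            dur_scale[member] *= mults["observation_duration"]
    # spans capped at 100 years: keeps the log-normal tail physically plausible
    durations = np.clip(np.round(durations * dur_scale).astype(int), 0, 36_500)
    gaps = rng_obs.integers(0, 365, size=len(obs_idx))
    end = ref - pd.to_timedelta(gaps, unit="D")
    start = end - pd.to_timedelta(durations, unit="D")
    obs = pd.DataFrame({
        "person_id": person_id[obs_idx],
        "start_date": start,
        "end_date": end,
    })

    if n == 0:
        persons = persons.astype({"birth_date": "datetime64[ns]", "death_date": "datetime64[ns]"})
        events = pd.DataFrame({"person_id": pd.Series(dtype=str),
                               "event_date": pd.Series(dtype="datetime64[ns]"),
                               "event_kind": pd.Series(dtype=str)})
        obs = pd.DataFrame({"person_id": pd.Series(dtype=str),
                            "start_date": pd.Series(dtype="datetime64[ns]"),
                            "end_date": pd.Series(dtype="datetime64[ns]")})

    cohort = Cohort(
        persons=persons.sort_values("person_id", kind="mergesort").reset_index(drop=True),
        events=events.sort_values(["person_id", "event_date", "event_kind"], kind="mergesort").reset_index(drop=True),
        observation_periods=obs.sort_values(["person_id", "start_date", "end_date"], kind="mergesort").reset_index(drop=True),
        reference_date=ref,
    )
    validate_cohort(cohort)
    return cohort


def planted_truth(config: SyntheticConfig) -> set[tuple[str, str]]:
    """The (group, filter_id) pairs where planted multipliers shift survival.

    Derived from the filter→element dependency map: a pair is in the truth set
    iff the group carries a non-unit multiplier on any element the filter
    depends on. With all multipliers at 1 the set is empty.
    """
    truth: set[tuple[str, str]] = set()
    for group, mults in config.group_multipliers.items():
        biased = {e for e, m in mults.items() if m != 1.0}
        if not biased:
            continue
        for fid, deps in FILTER_DEPENDENCIES.items():
            if deps & biased:
                truth.add((group, fid))
    return truth
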