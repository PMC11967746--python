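"""Availability audit: per-group tabulation, additivity, percentage convention."""

from __future__ import annotations

import math

import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cohortbias.audit import percent_remaining, run_audit, to_wide
from cohortbias.filters import OBS_SPANS, catalogue
from cohortbias.synth import SyntheticConfig, generate_cohort

from conftest import make_cohort


class TestPercentRemaining:
    @pytest.mark.parametrize(
        "remaining, baseline, expected",
        [
            # printed (count, total) pairs from a published availability table,
            # used as numeric fixtures
            (1_992_336, 4_031_307, 49.42),
            (5_166_379, 7_121_848, 72.54),
            (373_130, 4_031_307, 9.26),
            (58_264, 287_012, 20.30),
            (11_472, 502_364, 2.28),
            (1_252_219, 7_121_848, 17.58),
            (0, 100, 0.00),
            (100, 100, 100.00),
        ],
    )
    def test_two_decimal_half_away_from_zero(self, remaining, baseline, expected):
        assert percent_remaining(remaining, baseline) == expected

    def test_half_away_from_zero_not_bankers(self):
        # 0.125% must round up to 0.13, not to even (0.12)
        assert percent_remaining(125, 100_000) == 0.13

    def test_zero_baseline_rejected(self):
        with pytest.raises(ZeroDivisionError):
            percent_remaining(0, 0)

    @given(st.integers(1, 10_000), st.data())
    @settings(derandomize=True, max_examples=100)
    def test_bounds_and_monotonicity(self, baseline, data):
        remaining = data.draw(st.integers(0, baseline))
        pct = percent_remaining(remaining, baseline)
        assert 0.0 <= pct <= 100.0
        assert abs(pct - 100 * remaining / baseline) <= 0.005 + 1e-12


def _brute_force_counts(patients, filter_id, reference_date):
    """Independent per-patient predicate evaluation for the oracle cohort."""
    ref = pd.Timestamp(reference_date)
    survivors = set()
    for p in patients:
        if filter_id == "alive":
            ok = p["death"] is None or pd.Timestamp(p["death"]) > ref
        elif filter_id == "age_sex":
            ok = p["birth"] is not None and p["sex"] is not None
        elif filter_id == "has_address":
            ok = p["address"]
        elif filter_id in ("has_diagnosis", "has_medication", "has_outpatient_visit"):
            kind = filter_id.removeprefix("has_")
            ok = any(k == kind for k, _ in p["events"])
        elif filter_id.startswith("age_"):
            bound = int(filter_id.split("_")[-1])
            at_least = "_ge_" in filter_id
            ok = False
            if p["birth"] is not None:
                b = pd.Timestamp(p["birth"])
                for kind, date in p["events"]:
                    if kind != "diagnosis":
                        continue
                    d = pd.Timestamp(date)
                    age = d.year - b.year - ((d.month, d.day) < (b.month, b.day))
                    if (age >= bound) if at_least else (age <= bound):
                        ok = True
        elif filter_id in OBS_SPANS:
            need = OBS_SPANS[filter_id]
            spans = [(pd.Timestamp(e) - pd.Timestamp(s)).days for s, e in p["obs"]]
            ok = bool(spans) and max(spans) >= need
        else:  # pragma: no cover
            raise AssertionError(filter_id)
        if ok:
            survivors.add(p["pid"])
    return survivors


@pytest.fixture(scope="module")
def oracle_patients():
    """40 hand-parameterized patients: 4 races x 2 ethnicities x 5 patterns."""
    races = ["White", "Black or African", "Asian", "Unknown"]
    eths = ["Non-Hispanic or non-Latino", "Hispanic or Latino"]
    patterns = [
        # (birth, sex, death, address, events, obs periods)
        ("1980-01-01", "F", None, True,
         [("diagnosis", "2010-06-01"), ("medication", "2012-01-01")],
         [("2010-01-01", "2018-01-01")]),
        ("1950-01-01", "M", "2023-12-31", False,
         [("diagnosis", "2016-01-01"), ("outpatient_visit", "2016-01-02")],
         [("2016-01-01", "2016-01-15")]),
        (None, "F", None, True,
         [("diagnosis", "2020-01-01")],
         []),
        ("2005-01-01", None, None, False,
         [("medication", "2021-01-01")],
         [("2021-01-01", "2021-01-05")]),
        ("1935-06-01", "M", "2024-06-01", True,
         [("diagnosis", "2001-06-01"), ("diagnosis", "2022-01-01")],
         [("2000-01-01", "2007-01-01"), ("2020-01-01", "2020-03-01")]),
    ]
    patients = []
    i = 0
    for race in races:
        for eth in eths:
            for birth, sex, death, addr, events, obs in patterns:
                patients.append({
                    "pid": f"Q{i:02d}", "race": race, "eth": eth, "birth": birth,
                    "sex": sex, "death": death, "address": addr,
                    "events": events, "obs": obs,
                })
                i += 1
    return patients


@pytest.fixture(scope="module")
def oracle_cohort(oracle_patients):
    return make_cohort(
        [(p["pid"], p["birth"], p["sex"], p["race"], p["eth"], p["death"], p["address"])
         for p in oracle_patients],
        [(p["pid"], date, kind) for p in oracle_patients for kind, date in p["events"]],
        [(p["pid"], s, e) for p in oracle_patients for s, e in p["obs"]],
        reference_date="2024-01-01",
    )


class TestRunAudit:
    def test_matches_brute_force_enumeration(self, oracle_patients, oracle_cohort):
        table = run_audit(oracle_cohort)
        for spec in catalogue():
            survivors = _brute_force_counts(oracle_patients, spec.filter_id, "2024-01-01")
            by_race, by_eth = {}, {}
            for p in oracle_patients:
                if p["pid"] in survivors:
                    by_race[p["race"]] = by_race.get(p["race"], 0) + 1
                    by_eth[p["eth"]] = by_eth.get(p["eth"], 0) + 1
            sub = table[table["filter_id"] == spec.filter_id].set_index(["grouping", "group"])
            assert sub.loc[("all", "all"), "remaining_n"] == len(survivors)
            for race, n in by_race.items():
                assert sub.loc[("race", race), "remaining_n"] == n
            for eth, n in by_eth.items():
                assert sub.loc[("ethnicity", eth), "remaining_n"] == n

    def test_additivity_race_and_ethnicity(self, oracle_cohort):
        table = run_audit(oracle_cohort)
        for fid, sub in table.groupby("filter_id"):
            all_n = sub.loc[sub["grouping"] == "all", "remaining_n"].iloc[0]
            assert sub.loc[sub["grouping"] == "race", "remaining_n"].sum() == all_n
            assert sub.loc[sub["grouping"] == "ethnicity", "remaining_n"].sum() == all_n

    def test_all_baseline_is_total_cohort(self, oracle_cohort):
        table = run_audit(oracle_cohort)
        all_rows = table[table["grouping"] == "all"]
        assert (all_rows["baseline_n"] == len(oracle_cohort)).all()

    def test_saturated_cohort_reads_100_everywhere(self):
        cohort = make_cohort(
            [("S1", "1980-01-01", "F", "White", "Hispanic or Latino", None, True),
             ("S2", "1984-01-01", "M", "Asian", "Unknown", None, True)],
            [(pid, "2014-01-01", kind) for pid in ("S1", "S2")
             for kind in ("diagnosis", "medication", "outpatient_visit")],
            [(pid, "2010-01-01", "2020-01-01") for pid in ("S1", "S2")],
            reference_date="2024-01-01",
        )
        # ages at the 2014 diagnosis are 34 and 30: drop the age filters that
        # legitimately exclude them
        specs = [s for s in catalogue()
                 if s.filter_id not in ("age_le_21", "age_ge_65")]
        table = run_audit(cohort, specs)
        assert (table["remaining_pct"] == 100.0).all()

    def test_single_patient_failing_filter_reads_zero(self):
        cohort = make_cohort(
            [("Z1", "1980-01-01", "F", "Asian", "Hispanic or Latino", None, False)],
        )
        table = run_audit(cohort)
        sub = table[table["filter_id"] == "has_address"]
        assert set(sub["remaining_pct"]) == {0.0}
        assert {("race", "Asian"), ("ethnicity", "Hispanic or Latino"), ("all", "all")} <= \
            set(zip(sub["grouping"], sub["group"]))

    def test_groups_with_zero_baseline_are_omitted(self, oracle_cohort):
        table = run_audit(oracle_cohort)
        assert "Mixed" not in set(table["group"])

    def test_order_invariance(self, oracle_cohort):
        specs = catalogue()
        t1 = run_audit(oracle_cohort, specs)
        t2 = run_audit(oracle_cohort, list(reversed(specs)))
        key = ["grouping", "group", "filter_id"]
        pd.testing.assert_frame_equal(
            t1.sort_values(key).reset_index(drop=True),
            t2.sort_values(key).reset_index(drop=True),
        )

    def test_empty_spec_list_rejected(self, oracle_cohort):
        with pytest.raises(ValueError, match="non-empty"):
            run_audit(oracle_cohort, [])

    def test_wide_reshape_is_lossless(self, oracle_cohort):
        table = run_audit(oracle_cohort)
        wide = to_wide(table)
        for row in table.itertuples():
            assert wide.loc[row.filter_id, (row.grouping, row.group)] == row.remaining_pct


class TestAuditOnSynthetic:
    def test_additivity_across_random_cohorts(self):
        # spot-check on a handful here; the acceptance suite sweeps 200
        for seed in range(5):
            cohort = generate_cohort(SyntheticConfig(n_patients=1000, seed=seed))
            table = run_audit(cohort)
            for _, sub in table.groupby("filter_id"):
                all_n = sub.loc[sub["grouping"] == "all", "remaining_n"].iloc[0]
                assert sub.loc[sub["grouping"] == "race", "remaining_n"].sum() == all_n
                assert sub.loc[sub["grouping"] == "ethnicity", "remaining_n"].sum() == all_n
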