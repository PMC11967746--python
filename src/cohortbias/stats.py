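"""Binomial observed-vs-expected bias test with Bonferroni correction.

For each non-baseline group g and each filter, the survivors of g are compared
with the survivors of a baseline group b (White for race; non-Hispanic for
ethnicity), asking whether g's share among the combined survivors,

    observed = filtered_g / (filtered_g + filtered_b),

is lower than its pre-filter share,

    expected = total_g / (total_g + total_b).

Under the null that the filter removes patients at the same rate in both
groups, filtered_g is Binomial(filtered_g + filtered_b, expected); the exact
binomial tail gives the p-value. The default alternative ``less`` tests
whether the group is under-represented among survivors (disproportionately
excluded). P-values are Bonferroni-adjusted over all tests emitted for the
cohort run.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .audit import GROUPING_ETHNICITY, GROUPING_RACE

#: above this many trials the exact tail sum gives way to a normal approximation
EXACT_TRIALS_THRESHOLD = 10**7

DEFAULT_BASELINE_RACE = "White"
DEFAULT_BASELINE_ETHNICITY = "Non-Hispanic or non-Latino"

BIAS_COLUMNS = (
    "grouping", "group", "filter_id",
    "filtered_group_n", "filtered_baseline_n", "group_total_n", "baseline_total_n",
    "observed_prop", "expected_prop", "p_raw", "p_adj", "significant",
)


def observed_proportion(filtered_group_n: int, filtered_baseline_n: int) -> float:
    """Group share among the combined survivors of group + baseline."""
    trials = filtered_group_n + filtered_baseline_n
    if trials <= 0:
        raise ZeroDivisionError("no survivors in group or baseline: proportion undefined")
    return filtered_group_n / trials


def expected_proportion(group_total_n: int, baseline_total_n: int) -> float:
    """Group share of the combined pre-filter group + baseline population."""
    total = group_total_n + baseline_total_n
    if total <= 0:
        raise ZeroDivisionError("empty group and baseline: proportion undefined")
    return group_total_n / total


def binomial_bias_test(
    filtered_group_n: int,
    filtered_baseline_n: int,
    expected_prop: float,
    alternative: str = "less",
    exact_threshold: int = EXACT_TRIALS_THRESHOLD,
) -> float:
    """Exact binomial p-value for the observed group share vs its expected share.

    ``alternative="less"`` (the default) is the under-representation test; use
    ``"two_sided"`` for deviation in either direction. Above ``exact_threshold``
    trials a normal approximation with continuity correction is used.
    """
    if not 0.0 <= expected_prop <= 1.0:
        raise ValueError(f"expected_prop must lie in [0, 1], got {expected_prop}")
    if alternative not in ("less", "two_sided"):
        raise ValueError(f"alternative must be 'less' or 'two_sided', got {alternative!r}")
    k = int(filtered_group_n)
    n = int(filtered_group_n + filtered_baseline_n)
    if n <= 0:
        raise ValueError("trials must be positive; undefined test should be handled upstream")

    if n <= exact_threshold:
        if alternative == "less":
            return float(sps.binom.cdf(k, n, expected_prop))
        return float(sps.binomtest(k, n, expected_prop, alternative="two-sided").pvalue)

    # normal approximation, continuity corrected
    mu = n * expected_prop
    sigma = math.sqrt(n * expected_prop * (1.0 - expected_prop))
    if sigma == 0.0:
        return 1.0 if (expected_prop == 0.0) == (k == 0) or k == n else 0.0
    p_less = float(sps.norm.cdf((k + 0.5 - mu) / sigma))
    if alternative == "less":
        return p_less
    p_greater = float(sps.norm.sf((k - 0.5 - mu) / sigma))
    return min(1.0, 2.0 * min(p_less, p_greater))


def bonferroni_adjust(p_values: Iterable[float], m: int | None = None) -> list[float]:
    """Map each p to min(1, m·p); m defaults to the number of p-values."""
    ps = [float(p) for p in p_values]
    if any(not 0.0 <= p <= 1.0 for p in ps if not math.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = len(ps)
    if m < 1:
        raise ValueError(f"family size m must be >= 1, got {m}")
    if m < sum(not math.isnan(p) for p in ps):
        raise ValueError("family size m smaller than the number of tests")
    return [p if math.isnan(p) else min(1.0, m * p) for p in ps]


def run_bias_tests(
    table: pd.DataFrame,
    baseline_race: str = DEFAULT_BASELINE_RACE,
    baseline_ethnicity: str = DEFAULT_BASELINE_ETHNICITY,
    alpha: float = 0.05,
    alternative: str = "less",
) -> pd.DataFrame:
    """One bias test per (grouping, non-baseline group, filter) in an availability table.

    The Bonferroni family is the full set of applicable tests emitted for the
    cohort run (both groupings × all filters). Rows whose combined survivor
    count is zero are recorded with NaN p-values and excluded from the family.
    Baseline groups themselves are never tested.
    """
    baselines = {GROUPING_RACE: baseline_race, GROUPING_ETHNICITY: baseline_ethnicity}
    rows = []
    for grouping, baseline in baselines.items():
        sub = table[table["grouping"] == grouping]
        if sub.empty:
            continue
        if baseline not in set(sub["group"]):
            raise ValueError(f"baseline group {baseline!r} absent from {grouping} grouping")
        base = sub[sub["group"] == baseline].set_index("filter_id")
        for group in sub["group"].unique():
            if group == baseline:
                continue
            grp = sub[sub["group"] == group].set_index("filter_id")
            for fid in grp.index:
                fg = int(grp.loc[fid, "remaining_n"])
                fb = int(base.loc[fid, "remaining_n"])
                tg = int(grp.loc[fid, "baseline_n"])
                tb = int(base.loc[fid, "baseline_n"])
                exp = expected_proportion(tg, tb)
                if fg + fb == 0:
                    obs, p = math.nan, math.nan
                else:
                    obs = observed_proportion(fg, fb)
                    p = binomial_bias_test(fg, fb, exp, alternative=alternative)
                rows.append((grouping, group, fid, fg, fb, tg, tb, obs, exp, p, math.nan, False))

    result = pd.DataFrame(rows, columns=list(BIAS_COLUMNS))
    applicable = result["p_raw"].notna()
    m = int(applicable.sum())
    if m:
        result.loc[applicable, "p_adj"] = bonferroni_adjust(result.loc[applicable, "p_raw"], m)
        result.loc[applicable, "significant"] = result.loc[applicable, "p_adj"] < alpha
    return result
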