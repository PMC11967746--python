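"""Drop-off curves and publication-style output files.

A drop-off curve orders the filters by descending availability in the ``all``
group (ties broken by catalogue order) and lists, per group, the percentage of
patients remaining at each filter. The points are not cumulative — each filter
is independent — the ordering just eases visual comparison across groups.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from .audit import GROUPING_ALL, to_wide
from .filters import catalogue

PCT_FORMAT = "%.2f"
PVALUE_SIG_DIGITS = 6


def build_dropoff(table: pd.DataFrame) -> dict:
    """Per-grouping curve data from a long availability table.

    Filters are sorted by descending all-group remaining percentage, catalogue
    order breaking ties; group series carry the table's values unchanged.
    """
    all_rows = table[table["grouping"] == GROUPING_ALL]
    if all_rows.empty:
        raise ValueError("availability table has no 'all' group rows")
    cat_order = {s.filter_id: i for i, s in enumerate(catalogue())}
    ordered = sorted(
        all_rows.itertuples(),
        key=lambda r: (-r.remaining_pct, cat_order.get(r.filter_id, len(cat_order))),
    )
    filter_order = [r.filter_id for r in ordered]

    curves: dict = {"filter_order": filter_order, "groupings": {}}
    for grouping in table["grouping"].unique():
        sub = table[table["grouping"] == grouping]
        series = {}
        for group in sub["group"].unique():
            grp = sub[sub["group"] == group].set_index("filter_id")["remaining_pct"]
            series[group] = [float(grp[fid]) for fid in filter_order if fid in grp.index]
        curves["groupings"][grouping] = series
    return curves


def format_pvalue(p: float) -> str:
    """Scientific notation, 6 significant digits; NaN prints as empty."""
    if pd.isna(p):
        return ""
    return f"{p:.{PVALUE_SIG_DIGITS - 1}e}"


def write_outputs(
    out_dir: str | Path,
    availability: pd.DataFrame,
    bias: pd.DataFrame | None = None,
    summary: dict | None = None,
) -> dict[str, Path]:
    """Write the availability tables (long + wide), bias tests, curve JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    long_path = out_dir / "availability_long.csv"
    availability.to_csv(long_path, index=False, float_format=PCT_FORMAT, lineterminator="\n")
    paths["availability_long"] = long_path

    wide_path = out_dir / "availability_wide.csv"
    to_wide(availability).to_csv(wide_path, float_format=PCT_FORMAT, lineterminator="\n")
    paths["availability_wide"] = wide_path

    curve_path = out_dir / "dropoff_curves.json"
    curve_path.write_text(json.dumps(build_dropoff(availability), indent=2) + "\n")
    paths["dropoff_curves"] = curve_path

    if bias is not None:
        bias_out = bias.copy()
        for col in ("observed_prop", "expected_prop"):
            bias_out[col] = bias_out[col].map(lambda v: "" if pd.isna(v) else f"{v:.6f}")
        for col in ("p_raw", "p_adj"):
            bias_out[col] = bias_out[col].map(format_pvalue)
        bias_path = out_dir / "bias_tests.csv"
        bias_out.to_csv(bias_path, index=False, lineterminator="\n")
        paths["bias_tests"] = bias_path

    if summary is not None:
        summary_path = out_dir / "summary.json"
        summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
        paths["summary"] = summary_path
    return paths


def write_manifest(out_dir: str | Path, *, seed: int | None, config: dict | None,
                   inputs: dict | None = None) -> Path:
    """Run manifest: inputs, config hash, seed, package versions.

    Deliberately timestamp-free so identical-seed runs produce identical files.
    """
    import cohortbias

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config_json = json.dumps(config, sort_keys=True) if config is not None else None
    manifest = {
        "package": "cohortbias",
        "version": cohortbias.__version__,
        "pandas_version": pd.__version__,
        "seed": seed,
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest() if config_json else None,
        "config": config,
        "inputs": inputs or {},
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path
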