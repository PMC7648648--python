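"""Lineage-tracing clone statistics and cell-census summaries.

Clone tables record, per ovariole, the category of labeling observed in
a lineage-tracing experiment (e.g. unmarked, escort-cell clones only,
transient follicle clones, mosaic/full follicle epithelium).  The unit
of biological replication is the fly: frequencies are computed per fly
and compared between conditions with the classical pooled-variance
two-sample Student's t-test.  Census tables record per-germarium cell
counts for a marker and are summarized as mean +/- SD with derived
between-marker difference estimates.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from ._stats import pooled_t_test

CLONE_COLUMNS = ["fly_id", "condition", "ovariole_id", "category"]


def validate_clone_table(table: pd.DataFrame, categories: list[str]) -> pd.DataFrame:
    missing = set(CLONE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"clone table missing columns: {sorted(missing)}")
    if len(table) == 0:
        raise ValueError("empty clone table")
    unknown = sorted(set(table["category"]) - set(categories))
    if unknown:
        raise ValueError(f"unknown clone categories: {unknown}")
    dup = table.duplicated(subset=["condition", "fly_id", "ovariole_id"])
    if dup.any():
        raise ValueError("duplicate (fly_id, ovariole_id) within a condition")
    return table


def tally_clone_categories(table: pd.DataFrame, categories: list[str]) -> pd.DataFrame:
    """Per-condition category counts, proportions, and S.E.M. across flies.

    Proportion = ovarioles in the category / total ovarioles in the
    condition.  S.E.M. = SD (n-1) of the per-fly proportions divided by
    sqrt(number of flies); undefined (NaN, with a warning) for a single
    fly.
    """
    validate_clone_table(table, categories)
    rows = []
    for cond, sub in table.groupby("condition", sort=True):
        n_total = len(sub)
        flies = sub.groupby("fly_id")
        n_flies = flies.ngroups
        if n_flies < 2:
            warnings.warn(f"condition {cond!r} has a single fly; S.E.M. undefined")
        for cat in categories:
            count = int((sub["category"] == cat).sum())
            per_fly = flies.apply(
                lambda f: (f["category"] == cat).mean(), include_groups=False
            )
            sem = (
                float(per_fly.std(ddof=1) / np.sqrt(n_flies)) if n_flies >= 2 else np.nan
            )
            rows.append(
                {
                    "condition": cond,
                    "category": cat,
                    "count": count,
                    "proportion": count / n_total,
                    "sem": sem,
                    "n_flies": n_flies,
                    "n_ovarioles": n_total,
                }
            )
    return pd.DataFrame(rows)


def per_fly_frequency(
    table: pd.DataFrame, categories_of_interest: list[str], categories: list[str] | None = None
) -> pd.DataFrame:
    """Per-fly frequency of ovarioles in any category of interest.

    Returns one row per (condition, fly) with the fraction of that fly's
    ovarioles falling into the union of the categories of interest.
    """
    if categories is not None:
        validate_clone_table(table, categories)
    rows = []
    for (cond, fly), sub in table.groupby(["condition", "fly_id"], sort=True):
        freq = sub["category"].isin(categories_of_interest).mean()
        rows.append(
            {"condition": cond, "fly_id": fly, "frequency": float(freq), "n_ovarioles": len(sub)}
        )
    return pd.DataFrame(rows)


def compare_frequencies(freqs_a, freqs_b) -> tuple[float, int, float]:
    """Two-sided pooled-variance Student's t between two frequency groups.

    Returns (t, df, p) with df = n1 + n2 - 2.  Each group needs at least
    two values.  Welch's unequal-variance test is deliberately not the
    default; the classical equal-variance form is the convention for
    per-animal clone frequencies.
    """
    return pooled_t_test(np.asarray(freqs_a, float), np.asarray(freqs_b, float))


def population_census(census: pd.DataFrame) -> pd.DataFrame:
    """Per-marker mean and SD of per-germarium cell counts.

    Census rows are (germarium_id, marker, cell_count); SD uses the n-1
    denominator and is NaN (with a warning) for a single germarium.
    """
    for col in ("germarium_id", "marker", "cell_count"):
        if col not in census.columns:
            raise ValueError(f"census table missing column {col!r}")
    if (census["cell_count"] < 0).any():
        raise ValueError("negative cell counts in census")
    rows = []
    for marker, sub in census.groupby("marker", sort=True):
        n = len(sub)
        if n < 2:
            warnings.warn(f"marker {marker!r} has a single germarium; SD undefined")
        rows.append(
            {
                "marker": marker,
                "mean": float(sub["cell_count"].mean()),
                "sd": float(sub["cell_count"].std(ddof=1)) if n >= 2 else np.nan,
                "n": n,
            }
        )
    return pd.DataFrame(rows).set_index("marker")


def census_difference(
    stats: pd.DataFrame, marker_a: str, marker_b: str, integer: bool = False
) -> float | int:
    """Difference of mean census sizes, mean(A) - mean(B).

    With ``integer=True`` the estimate is rounded to the nearest whole
    cell (e.g. deriving the size of a subpopulation expressing marker A
    but not marker B).
    """
    for m in (marker_a, marker_b):
        if m not in stats.index:
            raise KeyError(f"marker {m!r} absent from census statistics")
    diff = float(stats.loc[marker_a, "mean"] - stats.loc[marker_b, "mean"])
    return int(round(diff)) if integer else diff


def coverage_ratio(total_cells: float, cells_per_unit: float) -> float:
    """Dataset coverage: total profiled cells per anatomical unit
    (e.g. cells sequenced / cells per ovariole)."""
    if cells_per_unit <= 0:
        raise ValueError("cells_per_unit must be > 0")
    return total_cells / cells_per_unit
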