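"""Deterministic arithmetic over compound, concentration and lipid tables.

These summaries reproduce the bookkeeping an analyst performs over the
outputs of quantitative platforms (NMR quantitation, lipid identification,
LC-MS/MS compound counting): per-class concentration totals with
3-significant-figure display rounding, subclass count totals checked
against any embedded total row, and cross-platform detection totals.
Sums use ``math.fsum`` so results are exactly reproducible at table scale.
"""

from __future__ import annotations

import importlib.resources as resources
import math
import os
from typing import Mapping

import pandas as pd

__all__ = [
    "round_sig",
    "load_concentration_table",
    "load_metabolite_concentrations",
    "load_count_table",
    "load_lipid_subclass_counts",
    "load_platform_counts",
    "class_totals",
    "subclass_total",
    "platform_total",
]

TOTAL_ROW_LABELS = ("total identifications", "total")


def round_sig(x: float, sig: int = 3) -> float:
    """Round to ``sig`` significant figures (display only; never mutates data)."""
    if x == 0:
        return 0.0
    from math import floor, log10

    return round(x, -int(floor(log10(abs(x)))) + (sig - 1))


def _read(path: str | os.PathLike) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, comment="#", dtype=str).fillna("")
    df.columns = [c.strip().lower() for c in df.columns]
    return df


def load_concentration_table(path: str | os.PathLike) -> pd.DataFrame:
    """Metabolite concentration table: name, formula, concentration_uM,
    compound_class (extra columns pass through)."""
    df = _read(path)
    required = {"name", "concentration_um", "compound_class"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    df["concentration_um"] = pd.to_numeric(df["concentration_um"])
    if (df["concentration_um"] < 0).any():
        raise ValueError(f"{path}: negative concentrations")
    return df


def load_metabolite_concentrations() -> pd.DataFrame:
    """Packaged NMR metabolite-concentration table (29 metabolites)."""
    ref = resources.files("fticrms.data").joinpath("metabolite_concentrations.csv")
    with resources.as_file(ref) as path:
        return load_concentration_table(path)


def load_count_table(path: str | os.PathLike) -> pd.DataFrame:
    """Count table: category, subclass, count (integers >= 0)."""
    df = _read(path)
    required = {"subclass", "count"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    df["count"] = pd.to_numeric(df["count"], downcast="integer")
    if (df["count"] < 0).any() or not (df["count"] == df["count"].astype(int)).all():
        raise ValueError(f"{path}: counts must be non-negative integers")
    df["count"] = df["count"].astype(int)
    return df


def load_lipid_subclass_counts() -> pd.DataFrame:
    """Packaged lipid subclass count table (19 subclasses + total row)."""
    ref = resources.files("fticrms.data").joinpath("lipid_subclass_counts.csv")
    with resources.as_file(ref) as path:
        return load_count_table(path)


def load_platform_counts() -> dict[str, int]:
    """Packaged per-platform detection counts."""
    ref = resources.files("fticrms.data").joinpath("platform_counts.csv")
    with resources.as_file(ref) as path:
        df = _read(path)
    return {row["platform"]: int(row["count"]) for _, row in df.iterrows()}


def class_totals(table: pd.DataFrame, sig: int = 3) -> pd.DataFrame:
    """Per-class concentration totals, ranked, with significant-figure display.

    Returns a frame indexed by compound class with columns total_um (full
    precision), total_um_3sf (display rounding) and rank (1 = largest).
    An empty table yields an empty frame.
    """
    if len(table) == 0:
        return pd.DataFrame(columns=["total_um", "total_um_3sf", "rank"])
    sums = {
        cls: math.fsum(grp["concentration_um"])
        for cls, grp in table.groupby("compound_class", sort=True)
    }
    out = pd.DataFrame(
        {"total_um": pd.Series(sums)},
    )
    out["total_um_3sf"] = [round_sig(v, sig) for v in out["total_um"]]
    out["rank"] = out["total_um"].rank(ascending=False, method="min").astype(int)
    out.index.name = "compound_class"
    return out.sort_values("rank")


def grand_total(table: pd.DataFrame) -> float:
    return math.fsum(table["concentration_um"]) if len(table) else 0.0


def subclass_total(table: pd.DataFrame) -> tuple[int, bool]:
    """Sum of subclass counts, excluding any embedded total row.

    Returns (total, consistent); ``consistent`` is False when an embedded
    total row disagrees with the recomputed sum (and True when no total
    row is present).
    """
    is_total = table["subclass"].str.strip().str.lower().isin(TOTAL_ROW_LABELS)
    body = table.loc[~is_total]
    total = int(body["count"].sum())
    embedded = table.loc[is_total, "count"]
    consistent = True
    if len(embedded):
        consistent = all(int(v) == total for v in embedded)
    return total, consistent


def platform_total(counts: Mapping[str, int]) -> int:
    """Total detections across platforms (e.g. NMR + LC-MS/MS modes + lipids)."""
    for k, v in counts.items():
        if int(v) != v or v < 0:
            raise ValueError(f"platform {k!r}: count must be a non-negative integer")
    return int(sum(int(v) for v in counts.values()))
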