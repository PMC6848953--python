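"""Mass-difference transformation networks over observed m/z values.

Every observed m/z value is a node; two nodes are connected when their
mass difference matches the exact mass of a named chemical transformation
(CH2 homologation, CO2 gain/loss, glycosylation, ...) within an absolute
tolerance (default 1 mDa — ppm tolerances are meaningless for a
difference).  Edges are undirected but serialized low-m/z -> high-m/z for
reproducibility; parallel edges with distinct transformation names are
allowed.  First-neighbor extraction around seed compounds (e.g. known
antimicrobials) yields candidate related chemistry one reaction away.
"""

from __future__ import annotations

import importlib.resources as resources
import logging
import os
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .chem_core import MolecularFormula, monoisotopic_mass
from .vankrevelen import ClassBin, classify

log = logging.getLogger(__name__)

__all__ = [
    "Transformation",
    "load_transformations",
    "default_transformations",
    "build_network",
    "first_neighbors",
    "annotate_network",
    "edge_table",
    "node_table",
    "write_graphml",
]

DEFAULT_TOL_DA = 0.001


@dataclass(frozen=True)
class Transformation:
    """A named exact mass difference, optionally backed by a formula."""

    name: str
    delta_mass: float
    formula: Optional[MolecularFormula] = None

    def __post_init__(self) -> None:
        if self.delta_mass <= 0:
            raise ValueError(f"transformation {self.name}: delta_mass must be positive")
        if self.formula is not None:
            theo = monoisotopic_mass(self.formula)
            if abs(self.delta_mass - theo) >= 1e-4:
                raise ValueError(
                    f"transformation {self.name}: delta_mass {self.delta_mass} "
                    f"inconsistent with formula mass {theo:.5f}"
                )


def _make_transformation(name: str, formula: str, delta: str) -> Transformation:
    """Build one dictionary row; the formula, when given, is authoritative."""
    mol = MolecularFormula.parse(formula) if formula else None
    if mol is not None:
        mass = monoisotopic_mass(mol)
        if delta and abs(float(delta) - mass) >= 1e-4:
            raise ValueError(
                f"row {name!r}: printed delta {delta} disagrees with formula mass {mass:.5f}"
            )
        return Transformation(name, mass, mol)
    if not delta:
        raise ValueError(f"row {name!r}: needs a formula and/or a delta_mass")
    return Transformation(name, float(delta))


def load_transformations(path: str | os.PathLike) -> list[Transformation]:
    """Load a transformation dictionary from delimited text.

    Columns: name, formula, delta_mass (formula and/or delta required;
    when both are present they must agree to 0.1 mDa — the mass is always
    recomputed from the formula).  Inconsistent rows raise.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, comment="#", dtype=str).fillna("")
    df.columns = [c.strip().lower() for c in df.columns]
    out = []
    for _, row in df.iterrows():
        out.append(
            _make_transformation(
                row["name"].strip(),
                row.get("formula", "").strip(),
                str(row.get("delta_mass", "")).strip(),
            )
        )
    return out


def default_transformations() -> list[Transformation]:
    """The packaged ~45-entry dictionary; every mass derives from a formula."""
    ref = resources.files("fticrms.data").joinpath("transformations.csv")
    with resources.as_file(ref) as path:
        return load_transformations(path)


def build_network(
    mz_values: Sequence[float],
    transformations: Optional[Sequence[Transformation]] = None,
    tol_da: float = DEFAULT_TOL_DA,
) -> nx.MultiGraph:
    """Connect every m/z pair whose difference matches a transformation.

    For each transformation t and ordered pair a < b with
    ``|b - a - delta_t| <= tol_da`` an edge (a, b) is added carrying the
    transformation name and the signed residual in Da.  Nodes are the
    (deduplicated) m/z values; input order is irrelevant.
    """
    if tol_da <= 0:
        raise ValueError("tol_da must be positive")
    if transformations is None:
        transformations = default_transformations()
    mz = np.unique(np.asarray(mz_values, dtype=float))
    g = nx.MultiGraph()
    g.add_nodes_from(float(v) for v in mz)
    for t in transformations:
        targets = mz + t.delta_mass
        lo = np.searchsorted(mz, targets - tol_da, side="left")
        hi = np.searchsorted(mz, targets + tol_da, side="right")
        for i in range(len(mz)):
            for j in range(lo[i], hi[i]):
                if j == i:
                    continue
                residual = float(mz[j] - mz[i] - t.delta_mass)
                g.add_edge(
                    float(mz[i]),
                    float(mz[j]),
                    key=t.name,
                    transformation=t.name,
                    residual_da=residual,
                )
    return g


def first_neighbors(
    network: nx.MultiGraph,
    seeds: Iterable[float],
) -> tuple[nx.MultiGraph, int]:
    """Subnetwork induced by seed nodes and everything one edge away.

    Seeds absent from the network are logged and skipped.  Returns the
    induced subgraph (seed/neighbor roles stored as node attributes) and
    the neighbor count excluding seeds, with shared neighbors counted
    once.
    """
    seed_set = set(float(s) for s in seeds)
    present = seed_set & set(network.nodes)
    missing = seed_set - present
    if missing:
        log.warning("first_neighbors: %d seed(s) not in network, skipped", len(missing))
    neighbor_set: set[float] = set()
    for s in present:
        neighbor_set.update(network.neighbors(s))
    neighbor_set -= present
    sub = network.subgraph(present | neighbor_set).copy()
    for node in sub.nodes:
        sub.nodes[node]["is_seed"] = node in present
        sub.nodes[node]["is_neighbor"] = node in neighbor_set
    return sub, len(neighbor_set)


def annotate_network(
    network: nx.MultiGraph,
    assignments: pd.DataFrame,
    bins: Optional[Sequence[ClassBin]] = None,
) -> nx.MultiGraph:
    """Attach formula and compound class to nodes from an assignment table.

    Nodes without an assigned formula are labeled ``"unknown"``.  The
    match is by m/z at 1e-9 Da (assignment tables and networks are built
    from the same peak list).
    """
    by_mz = {}
    for _, row in assignments.iterrows():
        if row.get("status") == "assigned" and row.get("formula"):
            by_mz[round(float(row["mz"]), 9)] = str(row["formula"])
    for node in network.nodes:
        f = by_mz.get(round(float(node), 9))
        if f:
            network.nodes[node]["formula"] = f
            network.nodes[node]["compound_class"] = classify(f, bins)
        else:
            network.nodes[node]["formula"] = "unknown"
            network.nodes[node]["compound_class"] = "unknown"
    return network


def class_tally(network: nx.MultiGraph, neighbors_only: bool = False) -> dict[str, int]:
    """Count annotated nodes per compound class (optionally neighbors only)."""
    tally: dict[str, int] = {}
    for node, data in network.nodes(data=True):
        if neighbors_only and not data.get("is_neighbor", False):
            continue
        cls = data.get("compound_class", "unknown")
        tally[cls] = tally.get(cls, 0) + 1
    return tally


def edge_table(network: nx.MultiGraph) -> pd.DataFrame:
    """Plain edge list: low_mz, high_mz, transformation, residual_da."""
    rows = []
    for u, v, data in network.edges(data=True):
        lo, hi = (u, v) if u <= v else (v, u)
        rows.append(
            {
                "low_mz": lo,
                "high_mz": hi,
                "transformation": data["transformation"],
                "residual_da": data["residual_da"],
            }
        )
    df = pd.DataFrame(rows, columns=["low_mz", "high_mz", "transformation", "residual_da"])
    return df.sort_values(["low_mz", "high_mz", "transformation"]).reset_index(drop=True)


def node_table(network: nx.MultiGraph) -> pd.DataFrame:
    """Node annotations: mz, formula, compound_class, is_seed, is_neighbor."""
    rows = []
    for node, data in network.nodes(data=True):
        rows.append(
            {
                "mz": float(node),
                "formula": data.get("formula", ""),
                "compound_class": data.get("compound_class", ""),
                "is_seed": bool(data.get("is_seed", False)),
                "is_neighbor": bool(data.get("is_neighbor", False)),
            }
        )
    df = pd.DataFrame(rows, columns=["mz", "formula", "compound_class", "is_seed", "is_neighbor"])
    return df.sort_values("mz").reset_index(drop=True)


def write_graphml(network: nx.MultiGraph, path: str | os.PathLike) -> None:
    nx.write_graphml(network, path)
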