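"""Van Krevelen coordinates and biochemical compound-class annotation.

Assigned formulas are placed on the van Krevelen plane (molar O:C on x,
molar H:C on y) and binned into rectangular compound-class regions that
proxy the major biochemical classes of natural organic matter.  The seven
default regions (lipid, unsaturated hydrocarbon, protein, amino sugar,
lignin, tannin, condensed aromatic) deliberately overlap in one corner;
a fixed priority order — the order the regions are listed — makes the
classification deterministic.  A carbohydrate region is shipped but
disabled by default since no range for it is part of the default scheme;
enable it via ``default_bins(include_carbohydrate=True)``.

Class abundances are count-based: the fraction of assigned formulas per
class within one sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
import yaml

from .chem_core import MolecularFormula

__all__ = [
    "VKCoordinates",
    "ClassBin",
    "default_bins",
    "load_bins",
    "vk_coordinates",
    "classify",
    "classify_table",
    "class_abundance",
    "UNCLASSIFIED",
]

UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class VKCoordinates:
    oc: float
    hc: float


@dataclass(frozen=True)
class ClassBin:
    """A rectangular van Krevelen region with explicit endpoint openness.

    ``oc_min_open``/``hc_min_open`` mean strict ``>`` at the lower edge;
    ``oc_max_closed``/``hc_max_closed`` mean ``<=`` (else strict ``<``) at
    the upper edge.  Lower priority number wins on overlap.
    """

    name: str
    oc_min: float
    oc_max: float
    hc_min: float
    hc_max: float
    oc_min_open: bool = False
    oc_max_closed: bool = True
    hc_min_open: bool = False
    hc_max_closed: bool = True
    priority: int = 0

    def contains(self, oc: float, hc: float) -> bool:
        lo_oc = oc > self.oc_min if self.oc_min_open else oc >= self.oc_min
        hi_oc = oc <= self.oc_max if self.oc_max_closed else oc < self.oc_max
        lo_hc = hc > self.hc_min if self.hc_min_open else hc >= self.hc_min
        hi_hc = hc <= self.hc_max if self.hc_max_closed else hc < self.hc_max
        return lo_oc and hi_oc and lo_hc and hi_hc


def default_bins(include_carbohydrate: bool = False) -> list[ClassBin]:
    """The seven standard compound-class regions, in priority order.

    lipid:                  0 < O:C <= 0.3,   1.5 <= H:C <= 2.5
    unsaturated hydrocarbon 0 <= O:C <= 0.125, 0.8 <= H:C < 2.5
    protein:                0.3 < O:C <= 0.55, 1.5 <= H:C <= 2.3
    amino sugar:            0.55 < O:C <= 0.7, 1.5 <= H:C <= 2.2
    lignin:                 0.125 < O:C <= 0.65, 0.8 <= H:C < 1.5
    tannin:                 0.65 < O:C <= 1.1, 0.8 <= H:C < 1.5
    condensed aromatic:     0 <= O:C <= 0.95, 0.2 <= H:C < 0.8

    The optional carbohydrate region (0.65 < O:C <= 1.1, 1.5 <= H:C <= 2.5)
    covers the sugar corner (e.g. glucose at O:C 1, H:C 2) that the seven
    standard regions leave unclassified.
    """
    bins = [
        ClassBin("lipid", 0.0, 0.3, 1.5, 2.5, oc_min_open=True, priority=0),
        ClassBin(
            "unsaturated_hydrocarbon", 0.0, 0.125, 0.8, 2.5, hc_max_closed=False, priority=1
        ),
        ClassBin("protein", 0.3, 0.55, 1.5, 2.3, oc_min_open=True, priority=2),
        ClassBin("amino_sugar", 0.55, 0.7, 1.5, 2.2, oc_min_open=True, priority=3),
        ClassBin("lignin", 0.125, 0.65, 0.8, 1.5, oc_min_open=True, hc_max_closed=False, priority=4),
        ClassBin("tannin", 0.65, 1.1, 0.8, 1.5, oc_min_open=True, hc_max_closed=False, priority=5),
        ClassBin("condensed_aromatic", 0.0, 0.95, 0.2, 0.8, hc_max_closed=False, priority=6),
    ]
    if include_carbohydrate:
        bins.append(ClassBin("carbohydrate", 0.65, 1.1, 1.5, 2.5, oc_min_open=True, priority=7))
    return bins


def load_bins(path: str) -> list[ClassBin]:
    """Load class regions from a YAML file (list of ClassBin field maps)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    bins = [ClassBin(**entry) for entry in raw]
    priorities = [b.priority for b in bins]
    if len(set(priorities)) != len(priorities):
        raise ValueError("class-bin priorities must be unique")
    return bins


def vk_coordinates(formula: MolecularFormula | str) -> VKCoordinates:
    """Molar O:C and H:C ratios of a formula; requires carbon."""
    if isinstance(formula, str):
        formula = MolecularFormula.parse(formula)
    return VKCoordinates(oc=formula.oc, hc=formula.hc)


def classify(
    formula: MolecularFormula | str,
    bins: Optional[Sequence[ClassBin]] = None,
) -> str:
    """Compound class of a formula, or ``"unclassified"``.

    The first region (lowest priority number) containing the formula's
    (O:C, H:C) point wins; carbon-free formulas are unclassified.
    """
    if isinstance(formula, str):
        formula = MolecularFormula.parse(formula)
    if formula.c <= 0:
        return UNCLASSIFIED
    if bins is None:
        bins = default_bins()
    oc, hc = formula.oc, formula.hc
    for b in sorted(bins, key=lambda b: b.priority):
        if b.contains(oc, hc):
            return b.name
    return UNCLASSIFIED


def classify_table(
    assignments: pd.DataFrame,
    bins: Optional[Sequence[ClassBin]] = None,
) -> pd.DataFrame:
    """Append van Krevelen columns (oc, hc, compound_class) to an
    assignment table; unknown rows get empty class fields."""
    out = assignments.copy()
    ocs, hcs, classes = [], [], []
    for f in out["formula"]:
        if not f:
            ocs.append(float("nan"))
            hcs.append(float("nan"))
            classes.append("unknown")
            continue
        mol = MolecularFormula.parse(f)
        if mol.c <= 0:
            ocs.append(float("nan"))
            hcs.append(float("nan"))
            classes.append(UNCLASSIFIED)
            continue
        ocs.append(mol.oc)
        hcs.append(mol.hc)
        classes.append(classify(mol, bins))
    out["oc"] = ocs
    out["hc"] = hcs
    out["compound_class"] = classes
    return out


def class_abundance(
    classified: pd.DataFrame | Iterable[str],
    bins: Optional[Sequence[ClassBin]] = None,
) -> dict[str, float]:
    """Count-based relative abundance of each compound class.

    Accepts a classified assignment table (uses rows with status
    "assigned") or a bare iterable of class labels.  Fractions over the
    class set plus ``"unclassified"`` sum to 1; raises if no formulas are
    assigned.
    """
    if isinstance(classified, pd.DataFrame):
        df = classified
        if "compound_class" not in df.columns:
            df = classify_table(df, bins)
        labels = df.loc[df["status"] == "assigned", "compound_class"].tolist()
    else:
        labels = list(classified)
    if not labels:
        raise ValueError("no assigned formulas; class abundance undefined")
    names = [b.name for b in (bins if bins is not None else default_bins())]
    counts: dict[str, int] = {name: 0 for name in names}
    counts[UNCLASSIFIED] = 0
    for lab in labels:
        counts[lab] = counts.get(lab, 0) + 1
    total = len(labels)
    return {name: cnt / total for name, cnt in counts.items()}


def abundance_matrix(per_sample: Mapping[str, Mapping[str, float]]) -> pd.DataFrame:
    """Stack per-sample class-abundance dicts into a samples x classes frame."""
    df = pd.DataFrame.from_dict(per_sample, orient="index").fillna(0.0)
    df.index.name = "sample_id"
    return df
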