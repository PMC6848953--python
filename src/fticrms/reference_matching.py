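"""Cross-checking observed m/z values against reference compound libraries.

Direct-injection FTICR-MS cannot separate isomers: compounds sharing a
molecular formula produce one m/z.  A reference list is therefore first
collapsed to distinct theoretical m/z values (isomer groups), then every
observed peak within a ppm tolerance of a theoretical m/z is reported.
The packaged fixture transcribes the 17 known antimicrobial compounds
confirmed in medicinal plants and shared with *Sphagnum fallax*; two
isomer pairs collapse them to 15 distinct deprotonated m/z values.
"""

from __future__ import annotations

import importlib.resources as resources
import os
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .chem_core import NEGATIVE, IonSpecies, MolecularFormula, mz_from_neutral, ppm_error
from .peaklist_io import SamplePeakList

__all__ = [
    "ReferenceCompound",
    "load_reference",
    "load_antimicrobial_reference",
    "distinct_mz",
    "match_peaks",
    "count_acid_names",
    "count_glycoside_names",
]


@dataclass(frozen=True)
class ReferenceCompound:
    name: str
    formula: MolecularFormula
    source: str = ""
    notes: str = ""

    @property
    def neutral_mass(self) -> float:
        return self.formula.mass


def load_reference(path: str | os.PathLike) -> list[ReferenceCompound]:
    """Load a reference compound list (columns name, formula, source[, notes]).

    Rows with unparseable formulas raise with the offending name."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, comment="#", dtype=str).fillna("")
    df.columns = [c.strip().lower() for c in df.columns]
    out = []
    for _, row in df.iterrows():
        try:
            mol = MolecularFormula.parse(row["formula"])
        except ValueError as exc:
            raise ValueError(f"reference row {row['name']!r}: {exc}") from exc
        out.append(
            ReferenceCompound(
                name=row["name"].strip(),
                formula=mol,
                source=row.get("source", "").strip(),
                notes=row.get("notes", "").strip(),
            )
        )
    return out


def load_antimicrobial_reference() -> list[ReferenceCompound]:
    """The packaged 17-compound antimicrobial reference list."""
    ref = resources.files("fticrms.data").joinpath("antimicrobial_reference.csv")
    with resources.as_file(ref) as path:
        return load_reference(path)


def distinct_mz(
    compounds: Sequence[ReferenceCompound],
    species: IonSpecies = NEGATIVE,
) -> pd.DataFrame:
    """One theoretical m/z per distinct formula, with isomer groups.

    Returns a frame with columns formula, theoretical_mz, isomer_group
    (0-based id in ascending m/z order) and members (compound names
    sharing the formula, input order preserved).
    """
    if not compounds:
        raise ValueError("at least one reference compound is required")
    groups: dict[str, list[ReferenceCompound]] = {}
    for comp in compounds:
        groups.setdefault(str(comp.formula), []).append(comp)
    rows = []
    for formula_str, members in groups.items():
        mz = mz_from_neutral(members[0].neutral_mass, species)
        rows.append(
            {
                "formula": formula_str,
                "theoretical_mz": mz,
                "members": [m.name for m in members],
                "n_isomers": len(members),
            }
        )
    df = pd.DataFrame(rows).sort_values("theoretical_mz").reset_index(drop=True)
    df.insert(2, "isomer_group", range(len(df)))
    return df


def match_peaks(
    sample: SamplePeakList,
    compounds: Sequence[ReferenceCompound],
    species: IonSpecies = NEGATIVE,
    tol_ppm: float = 1.0,
) -> pd.DataFrame:
    """Match observed peaks to reference m/z values within ``tol_ppm``.

    Every (theoretical m/z, observed peak) pair inside the tolerance is
    reported; the observed peak nearest each theoretical m/z is flagged
    ``primary``.  Unmatched references appear with status "unmatched" and
    empty observation fields.  Rows are sorted by reference name for
    reproducibility.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    refs = distinct_mz(compounds, species)
    mz = sample.mz
    rows = []
    for _, ref in refs.iterrows():
        theo = float(ref["theoretical_mz"])
        tol_da = theo * tol_ppm * 1e-6
        lo = np.searchsorted(mz, theo - tol_da, side="left")
        hi = np.searchsorted(mz, theo + tol_da, side="right")
        hits = [float(mz[k]) for k in range(lo, hi)]
        if not hits:
            for name in ref["members"]:
                rows.append(
                    {
                        "name": name,
                        "formula": ref["formula"],
                        "theoretical_mz": theo,
                        "observed_mz": float("nan"),
                        "error_ppm": float("nan"),
                        "isomer_group": int(ref["isomer_group"]),
                        "primary": False,
                        "status": "unmatched",
                    }
                )
            continue
        nearest = min(hits, key=lambda v: abs(v - theo))
        for obs in hits:
            for name in ref["members"]:
                rows.append(
                    {
                        "name": name,
                        "formula": ref["formula"],
                        "theoretical_mz": theo,
                        "observed_mz": obs,
                        "error_ppm": ppm_error(obs, theo),
                        "isomer_group": int(ref["isomer_group"]),
                        "primary": obs == nearest,
                        "status": "matched",
                    }
                )
    return (
        pd.DataFrame(
            rows,
            columns=[
                "name",
                "formula",
                "theoretical_mz",
                "observed_mz",
                "error_ppm",
                "isomer_group",
                "primary",
                "status",
            ],
        )
        .sort_values(["name", "observed_mz"])
        .reset_index(drop=True)
    )


def count_acid_names(compounds: Iterable[ReferenceCompound]) -> int:
    """References whose name contains the token "acid" (case-insensitive)."""
    return sum(1 for c in compounds if "acid" in c.name.lower())


def count_glycoside_names(compounds: Iterable[ReferenceCompound]) -> int:
    """References named as glycosides/glucosides (sugar derivatives)."""
    return sum(
        1
        for c in compounds
        if "glycoside" in c.name.lower() or "glucoside" in c.name.lower()
    )
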