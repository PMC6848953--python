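"""CHONSP molecular-formula assignment from exact neutral masses.

Candidate formulas are enumerated inside configurable element bounds and a
ppm mass window, filtered by chemical validity rules (one phosphorus
requires at least four oxygens; double-bond equivalents must be
non-negative), and the winner is chosen by fewest heteroatoms (N+S+P),
then lowest absolute ppm error, then lexicographic formula string — a
fully deterministic selection mirroring the hierarchical
CHO-before-heteroatom preference of compound-identification algorithms
for natural organic matter.

The enumerator avoids a full six-dimensional grid: it loops over the
heteroatoms and oxygen, then solves carbon and hydrogen directly from the
residual mass (for any C the compatible H count is unique because the
hydrogen mass far exceeds any sub-ppm window).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

from .chem_core import (
    MONOISOTOPIC_MASS,
    NEGATIVE,
    IonSpecies,
    MolecularFormula,
    neutral_from_mz,
    ppm_error,
)
from .peaklist_io import SamplePeakList

__all__ = [
    "ElementBounds",
    "FormulaAssignment",
    "DEFAULT_BOUNDS",
    "dbe",
    "enumerate_candidates",
    "select_formula",
    "assign_mass",
    "assign_sample",
]

_MC = MONOISOTOPIC_MASS["C"]
_MH = MONOISOTOPIC_MASS["H"]
_MN = MONOISOTOPIC_MASS["N"]
_MO = MONOISOTOPIC_MASS["O"]
_MP = MONOISOTOPIC_MASS["P"]
_MS = MONOISOTOPIC_MASS["S"]


@dataclass(frozen=True)
class ElementBounds:
    """Inclusive per-element count ranges for candidate enumeration."""

    c: tuple[int, int] = (1, 100)
    h: tuple[int, int] = (0, 200)
    o: tuple[int, int] = (0, 50)
    n: tuple[int, int] = (0, 5)
    s: tuple[int, int] = (0, 2)
    p: tuple[int, int] = (0, 2)

    def __post_init__(self) -> None:
        for sym in "chonsp":
            lo, hi = getattr(self, sym)
            if lo < 0 or hi < lo:
                raise ValueError(f"invalid bounds for {sym.upper()}: [{lo}, {hi}]")

    def combination_count(self) -> int:
        """Combinations the enumerator may visit (H is solved, not looped)."""
        out = 1
        for sym in "consp":
            lo, hi = getattr(self, sym)
            out *= hi - lo + 1
        return out

    @classmethod
    def parse(cls, text: str) -> "ElementBounds":
        """Parse ``"C:1-100,H:0-200,..."`` style bound strings."""
        kwargs = {}
        for part in text.split(","):
            sym, rng = part.split(":")
            lo, hi = rng.split("-")
            kwargs[sym.strip().lower()] = (int(lo), int(hi))
        return cls(**kwargs)


DEFAULT_BOUNDS = ElementBounds()

#: Refuse enumerations whose raw grid would be astronomically large.
MAX_RAW_COMBINATIONS = 10**7


def dbe(formula: MolecularFormula) -> float:
    """Double-bond equivalents: C - H/2 + N/2 + P/2 + 1."""
    return formula.c - formula.h / 2 + formula.n / 2 + formula.p / 2 + 1


@dataclass(frozen=True)
class FormulaAssignment:
    """A candidate (or selected) formula for one neutral mass."""

    mz: float
    neutral_mass: float
    formula: MolecularFormula
    error_ppm: float
    heteroatom_count: int
    dbe: float

    @property
    def formula_str(self) -> str:
        return str(self.formula)


def _sort_key(a: FormulaAssignment) -> tuple[int, float, str]:
    # Heteroatom minimization precedes error minimization: CHONSP space at
    # sub-ppm windows above ~300 Da contains many heteroatom-rich formulas
    # closer in mass than the true (usually CHO-dominated) composition, so
    # preferring the leanest composition is what makes assignment unique.
    return (a.heteroatom_count, abs(a.error_ppm), a.formula_str)


def enumerate_candidates(
    neutral_mass: float,
    tol_ppm: float = 1.0,
    bounds: ElementBounds = DEFAULT_BOUNDS,
    mz: float | None = None,
    enforce_dbe: bool = True,
    even_electron: bool = True,
) -> list[FormulaAssignment]:
    """All in-bounds formulas within ``tol_ppm`` (strict) of a neutral mass.

    Validity filters: one or more phosphorus atoms require at least four
    oxygens; DBE must be non-negative (opt-out via ``enforce_dbe``); the
    neutral must be a closed-shell molecule, i.e. DBE an integer
    (equivalently H+N+P even) — metabolites are not radicals (opt-out via
    ``even_electron``).  Results are sorted by the selection order
    (heteroatom count, |ppm error|, formula string).
    """
    if not 0 < neutral_mass <= 2000:
        raise ValueError(f"neutral mass {neutral_mass} outside (0, 2000] Da")
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    if bounds.combination_count() > MAX_RAW_COMBINATIONS:
        raise ValueError(
            "element bounds span too many combinations; tighten the ranges "
            "(heteroatom and oxygen maxima dominate the cost)"
        )
    tol_da = neutral_mass * tol_ppm * 1e-6
    upper = neutral_mass + tol_da
    cmin, cmax = bounds.c
    hmin, hmax = bounds.h
    out: list[FormulaAssignment] = []
    mz_val = mz if mz is not None else neutral_mass
    for n_cnt in range(bounds.n[0], bounds.n[1] + 1):
        mass_n = n_cnt * _MN
        if mass_n > upper:
            break
        for s_cnt in range(bounds.s[0], bounds.s[1] + 1):
            mass_ns = mass_n + s_cnt * _MS
            if mass_ns > upper:
                break
            for p_cnt in range(bounds.p[0], bounds.p[1] + 1):
                mass_nsp = mass_ns + p_cnt * _MP
                if mass_nsp > upper:
                    break
                o_lo = max(bounds.o[0], 4 if p_cnt >= 1 else 0)
                for o_cnt in range(o_lo, bounds.o[1] + 1):
                    hetero_mass = mass_nsp + o_cnt * _MO
                    if hetero_mass > upper:
                        break
                    rem = neutral_mass - hetero_mass
                    # feasible carbon window given H in [hmin, hmax]
                    c_hi = min(cmax, int((rem + tol_da - hmin * _MH) // _MC))
                    c_lo = max(cmin, math.ceil((rem - tol_da - hmax * _MH) / _MC))
                    for c_cnt in range(c_lo, c_hi + 1):
                        h_float = (rem - c_cnt * _MC) / _MH
                        h_cnt = round(h_float)
                        if h_cnt < hmin or h_cnt > hmax:
                            continue
                        if even_electron and (h_cnt + n_cnt + p_cnt) % 2:
                            continue
                        mass = hetero_mass + c_cnt * _MC + h_cnt * _MH
                        err = ppm_error(neutral_mass, mass)
                        if abs(err) >= tol_ppm:
                            continue
                        f = MolecularFormula(c=c_cnt, h=h_cnt, n=n_cnt, o=o_cnt, p=p_cnt, s=s_cnt)
                        d = dbe(f)
                        if enforce_dbe and d < 0:
                            continue
                        out.append(
                            FormulaAssignment(
                                mz=mz_val,
                                neutral_mass=neutral_mass,
                                formula=f,
                                error_ppm=err,
                                heteroatom_count=f.heteroatom_count,
                                dbe=d,
                            )
                        )
    out.sort(key=_sort_key)
    return out


def select_formula(candidates: Iterable[FormulaAssignment]) -> Optional[FormulaAssignment]:
    """Pick the winner: fewest heteroatoms, then lowest |ppm error|, then
    lexicographic formula string.  ``None`` for an empty candidate set."""
    best = None
    for cand in candidates:
        if best is None or _sort_key(cand) < _sort_key(best):
            best = cand
    return best


def assign_mass(
    neutral_mass: float,
    tol_ppm: float = 1.0,
    bounds: ElementBounds = DEFAULT_BOUNDS,
    mz: float | None = None,
) -> Optional[FormulaAssignment]:
    """Enumerate and select in one step."""
    return select_formula(enumerate_candidates(neutral_mass, tol_ppm, bounds, mz=mz))


def assign_sample(
    sample: SamplePeakList,
    species: IonSpecies = NEGATIVE,
    tol_ppm: float = 1.0,
    bounds: ElementBounds = DEFAULT_BOUNDS,
) -> pd.DataFrame:
    """Assign every peak of a (filtered, calibrated) sample.

    Returns one row per peak with columns sample_id, mz, neutral_mass,
    formula, error_ppm, heteroatoms, dbe and status ("assigned" or
    "unknown"); unknown rows carry empty formula fields.
    """
    rows = []
    for mz_val in sample.mz:
        neutral = neutral_from_mz(float(mz_val), species)
        best = assign_mass(neutral, tol_ppm, bounds, mz=float(mz_val))
        if best is None:
            rows.append(
                {
                    "sample_id": sample.sample_id,
                    "mz": float(mz_val),
                    "neutral_mass": neutral,
                    "formula": "",
                    "error_ppm": float("nan"),
                    "heteroatoms": -1,
                    "dbe": float("nan"),
                    "status": "unknown",
                }
            )
        else:
            rows.append(
                {
                    "sample_id": sample.sample_id,
                    "mz": float(mz_val),
                    "neutral_mass": neutral,
                    "formula": best.formula_str,
                    "error_ppm": best.error_ppm,
                    "heteroatoms": best.heteroatom_count,
                    "dbe": best.dbe,
                    "status": "assigned",
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "mz",
            "neutral_mass",
            "formula",
            "error_ppm",
            "heteroatoms",
            "dbe",
            "status",
        ],
    )
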