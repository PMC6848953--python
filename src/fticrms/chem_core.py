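"""Molecular formulas over {C, H, O, N, S, P} and exact-mass arithmetic.

Everything downstream of a peak list — internal calibration, formula
assignment, van Krevelen classification, transformation networks, reference
matching — reduces to sub-ppm arithmetic on monoisotopic masses of small
CHONSP formulas.  This module holds the single atomic-mass table, the
formula type, and the ion/neutral mass conversions for singly charged
(de)protonated species.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping

__all__ = [
    "ELEMENTS",
    "MONOISOTOPIC_MASS",
    "PROTON_MASS",
    "ELECTRON_MASS",
    "MolecularFormula",
    "IonSpecies",
    "NEGATIVE",
    "POSITIVE",
    "monoisotopic_mass",
    "mz_from_neutral",
    "neutral_from_mz",
    "ppm_error",
]

#: Elements allowed in assignments, in Hill order (C, H, then alphabetical).
ELEMENTS: tuple[str, ...] = ("C", "H", "N", "O", "P", "S")

#: Monoisotopic masses of the most abundant isotope, Da (CODATA/AME).
#: 12C is exactly 12 by definition of the unified atomic mass unit.
MONOISOTOPIC_MASS: Mapping[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "S": 31.97207100,
}

PROTON_MASS: float = 1.007276466621  # Da
ELECTRON_MASS: float = 0.000548579909  # Da

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class MolecularFormula:
    """Immutable element-count vector over C, H, N, O, P, S.

    Counts are non-negative integers; an absent element has count 0.
    Supports element-wise addition/scaling so transformation arithmetic
    (e.g. repeated CH2 additions) stays in formula space.
    """

    c: int = 0
    h: int = 0
    n: int = 0
    o: int = 0
    p: int = 0
    s: int = 0

    def __post_init__(self) -> None:
        for sym in ELEMENTS:
            cnt = getattr(self, sym.lower())
            if not isinstance(cnt, int) or cnt < 0:
                raise ValueError(
                    f"element count {sym}={cnt!r} must be a non-negative integer"
                )

    # -- construction -------------------------------------------------

    @classmethod
    def parse(cls, text: str) -> "MolecularFormula":
        """Parse a Hill-style string such as ``"C18H34O2"`` or ``"CH4O"``.

        An omitted count means 1.  Elements outside {C,H,O,N,S,P} are
        rejected; so is any unparseable residue.
        """
        text = text.strip()
        counts: dict[str, int] = {}
        pos = 0
        for match in _FORMULA_TOKEN.finditer(text):
            if not match.group(0):
                continue
            if match.start() != pos:
                raise ValueError(f"unparseable formula {text!r}")
            pos = match.end()
            sym, num = match.group(1), match.group(2)
            if sym not in ELEMENTS:
                raise ValueError(f"unsupported element {sym!r} in {text!r}")
            counts[sym] = counts.get(sym, 0) + (int(num) if num else 1)
        if pos != len(text) or (text and not counts):
            raise ValueError(f"unparseable formula {text!r}")
        return cls.from_counts(counts)

    @classmethod
    def from_counts(cls, counts: Mapping[str, int]) -> "MolecularFormula":
        unknown = set(counts) - set(ELEMENTS)
        if unknown:
            raise ValueError(f"unsupported element(s) {sorted(unknown)}")
        return cls(**{sym.lower(): int(counts.get(sym, 0)) for sym in ELEMENTS})

    # -- views ---------------------------------------------------------

    @property
    def counts(self) -> dict[str, int]:
        return {sym: getattr(self, sym.lower()) for sym in ELEMENTS}

    @property
    def heteroatom_count(self) -> int:
        """Number of N + S + P atoms."""
        return self.n + self.s + self.p

    @property
    def oc(self) -> float:
        """Molar O:C ratio; requires C > 0."""
        if self.c <= 0:
            raise ValueError("O:C undefined for formulas without carbon")
        return self.o / self.c

    @property
    def hc(self) -> float:
        """Molar H:C ratio; requires C > 0."""
        if self.c <= 0:
            raise ValueError("H:C undefined for formulas without carbon")
        return self.h / self.c

    def __str__(self) -> str:
        parts = []
        for sym in ELEMENTS:
            cnt = getattr(self, sym.lower())
            if cnt == 1:
                parts.append(sym)
            elif cnt > 1:
                parts.append(f"{sym}{cnt}")
        return "".join(parts)

    # -- arithmetic ----------------------------------------------------

    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        return MolecularFormula(
            *(getattr(self, a) + getattr(other, a) for a in "chnops")
        )

    def __mul__(self, k: int) -> "MolecularFormula":
        if not isinstance(k, int) or k < 0:
            raise ValueError("formula scaling requires a non-negative integer")
        return MolecularFormula(*(getattr(self, a) * k for a in "chnops"))

    __rmul__ = __mul__

    @property
    def mass(self) -> float:
        return monoisotopic_mass(self)


@dataclass(frozen=True)
class IonSpecies:
    """Singly charged (de)protonated ion convention.

    Negative-mode electrospray of organic matter produces [M-H]- ions:
    m/z = M - proton mass.  Positive mode [M+H]+: m/z = M + proton mass.
    The electron mass is folded into the proton-mass convention, which
    keeps computed neutral masses within the instrument's <1 ppm band.
    """

    polarity: str  # "negative" | "positive"
    charge: int = 1

    def __post_init__(self) -> None:
        if self.polarity not in ("negative", "positive"):
            raise ValueError(f"unknown polarity {self.polarity!r}")
        if abs(self.charge) != 1:
            raise ValueError("only singly charged species are supported")

    @property
    def adduct(self) -> str:
        return "[M-H]-" if self.polarity == "negative" else "[M+H]+"

    @property
    def mass_shift(self) -> float:
        """Signed Da shift from neutral mass to m/z."""
        return -PROTON_MASS if self.polarity == "negative" else PROTON_MASS


NEGATIVE = IonSpecies("negative")
POSITIVE = IonSpecies("positive")


def monoisotopic_mass(formula: MolecularFormula | str | Mapping[str, int]) -> float:
    """Exact (monoisotopic) neutral mass of a formula in Da."""
    if isinstance(formula, str):
        formula = MolecularFormula.parse(formula)
    elif isinstance(formula, Mapping):
        formula = MolecularFormula.from_counts(formula)
    return sum(
        cnt * MONOISOTOPIC_MASS[sym] for sym, cnt in formula.counts.items() if cnt
    )


def mz_from_neutral(mass: float, species: IonSpecies = NEGATIVE) -> float:
    """m/z of the singly charged (de)protonated ion of a neutral mass."""
    if mass <= 0:
        raise ValueError(f"neutral mass must be positive, got {mass}")
    return mass + species.mass_shift


def neutral_from_mz(mz: float, species: IonSpecies = NEGATIVE) -> float:
    """Neutral monoisotopic mass recovered from an observed m/z.

    An ion lighter than a proton cannot be a (de)protonated molecule, so
    such m/z values are rejected in either polarity.
    """
    if mz <= PROTON_MASS:
        raise ValueError(f"m/z {mz} is too small for a singly charged molecular ion")
    mass = mz - species.mass_shift
    if mass <= 0:
        raise ValueError(f"m/z {mz} implies a non-positive neutral mass")
    return mass


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass error in parts-per-million."""
    if theoretical <= 0:
        raise ValueError("theoretical mass must be positive")
    return (observed - theoretical) / theoretical * 1e6


def mass_of(formulas: Iterable[str]) -> list[float]:
    """Convenience: monoisotopic masses for an iterable of formula strings."""
    return [monoisotopic_mass(f) for f in formulas]
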