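"""Ground-truth-annotated synthetic FTICR-MS peak lists and summary tables.

The generator emulates negative-mode direct-injection spectra of plant
extracts: thousands of singly charged deprotonated CHONSP ions spanning
the van Krevelen compound classes over the 100-1200 m/z acquisition
window, with sub-ppm random mass error, optional linear-in-m/z systematic
drift, log-normal intensity and S/N distributions, planted CH2 homologous
ladders, planted transformation chains, reference spike-ins, and
formula-free contaminant peaks (verified against the assignment enumerator
at generation time so they form a true-negative set).

Every draw flows from one seed through named substreams, so identical
specs give byte-identical outputs and changing one component's draws does
not cascade into the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .chem_core import NEGATIVE, IonSpecies, MolecularFormula, mz_from_neutral
from .formula_assignment import DEFAULT_BOUNDS, ElementBounds, enumerate_candidates
from .peaklist_io import SamplePeakList
from .reference_matching import ReferenceCompound
from .transformation_network import default_transformations
from .vankrevelen import ClassBin, classify, default_bins

__all__ = [
    "SyntheticSpec",
    "generate_sample",
    "generate_concentration_table",
    "generate_lipid_counts",
]

#: Substream labels, fixed so adding a component never reshuffles the others.
_STREAMS = (
    "formulas",
    "errors",
    "intensity",
    "sn",
    "contaminants",
    "series",
    "chains",
    "spikes",
    "tables",
)

#: Default class mixture of a plant/organic-matter extract: lignin-like
#: polyphenols dominate, with substantial lipid- and protein-like fractions.
DEFAULT_MIXTURE: dict[str, float] = {
    "lignin": 0.35,
    "lipid": 0.15,
    "protein": 0.15,
    "tannin": 0.10,
    "condensed_aromatic": 0.10,
    "amino_sugar": 0.05,
    "unsaturated_hydrocarbon": 0.05,
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic negative-mode FTICR-MS sample."""

    seed: int = 0
    sample_id: str = "synthetic"
    n_compounds: int = 500
    mass_range: tuple[float, float] = (120.0, 900.0)
    class_mixture: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_MIXTURE))
    #: systematic ppm drift e(mz) = drift_a + drift_b * mz
    drift_a: float = 0.0
    drift_b: float = 0.0
    jitter_ppm: float = 0.2
    #: log-normal intensity: median ~1e4, spread ~x3
    intensity_mu: float = 9.2
    intensity_sigma: float = 1.2
    #: log-normal S/N: median ~30 (a few % fall below the S/N 7 threshold)
    sn_mu: float = 3.4
    sn_sigma: float = 0.8
    contaminant_fraction: float = 0.05
    n_series: int = 0
    series_length: int = 6
    n_chains: int = 0
    chain_length: int = 4
    chain_transformations: tuple[str, ...] = ("CO2", "CH2O", "H2O", "acetic_acid")
    spike_references: tuple[ReferenceCompound, ...] = ()
    bounds: ElementBounds = DEFAULT_BOUNDS
    species: IonSpecies = NEGATIVE

    def __post_init__(self) -> None:
        if not 0 <= self.contaminant_fraction <= 1:
            raise ValueError("contaminant_fraction must be in [0, 1]")
        total = sum(self.class_mixture.values())
        if any(f < 0 or f > 1 for f in self.class_mixture.values()) or total > 1 + 1e-9:
            raise ValueError("class mixture fractions must lie in [0,1] and sum to <= 1")


def _streams(seed: int) -> dict[str, np.random.Generator]:
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(_STREAMS))
    return {name: np.random.default_rng(child) for name, child in zip(_STREAMS, children)}


def _bin_by_name(name: str) -> ClassBin:
    for b in default_bins(include_carbohydrate=True):
        if b.name == name:
            return b
    raise ValueError(f"unknown compound class {name!r}")


_EPS = 0.02  # margin inside bin edges so integer rounding cannot flip the class


def _sample_formula_in_class(
    rng: np.random.Generator,
    cls: str,
    spec: SyntheticSpec,
    seen: set[str],
    max_tries: int = 400,
) -> MolecularFormula:
    """Rejection-sample a CHONSP formula classified into ``cls``.

    Draw C, then target O:C and H:C uniformly inside the class bin (with a
    margin), round to integer O and H, optionally decorate with N/S, and
    keep only formulas that classify back into the class, fall in the
    configured neutral-mass range, respect the element bounds, and are new.
    """
    b = _bin_by_name(cls)
    oc_lo = b.oc_min + _EPS
    oc_hi = b.oc_max - _EPS if b.oc_max > b.oc_min + 2 * _EPS else b.oc_max
    hc_lo = b.hc_min + _EPS
    hc_hi = b.hc_max - _EPS
    for _ in range(max_tries):
        c = int(rng.integers(6, 41))
        oc = float(rng.uniform(oc_lo, oc_hi))
        hc = float(rng.uniform(hc_lo, hc_hi))
        o = int(round(oc * c))
        h = int(round(hc * c))
        n = int(rng.integers(0, 3)) if rng.random() < 0.25 else 0
        s = 1 if rng.random() < 0.04 else 0
        if (h + n) % 2:  # closed-shell molecules only: H+N must be even
            h += 1 if h + 1 <= round((hc + 0.02) * c) or h == 0 else -1
        f = MolecularFormula(c=c, h=h, n=n, o=o, s=s)
        if c - h / 2 + n / 2 + 1 < 0:  # chemically invalid (negative DBE)
            continue
        if not (
            spec.bounds.c[0] <= c <= spec.bounds.c[1]
            and spec.bounds.h[0] <= h <= spec.bounds.h[1]
            and spec.bounds.o[0] <= o <= spec.bounds.o[1]
            and n <= spec.bounds.n[1]
            and s <= spec.bounds.s[1]
        ):
            continue
        if classify(f) != cls:
            continue
        mass = f.mass
        if not spec.mass_range[0] <= mass <= spec.mass_range[1]:
            continue
        if str(f) in seen:
            continue
        seen.add(str(f))
        return f
    raise ValueError(
        f"could not draw a formula for class {cls!r} inside the bounds/mass range"
    )


def _class_counts(spec: SyntheticSpec) -> dict[str, int]:
    """Deterministic largest-remainder allocation of n_compounds to classes;
    any mixture remainder is spread uniformly over the named classes."""
    names = list(spec.class_mixture.keys())
    fracs = np.array([spec.class_mixture[k] for k in names], dtype=float)
    leftover = 1.0 - fracs.sum()
    if leftover > 1e-9:
        fracs = fracs + leftover / len(fracs)
    raw = fracs * spec.n_compounds
    counts = np.floor(raw).astype(int)
    remainder = spec.n_compounds - counts.sum()
    order = np.argsort(-(raw - counts))
    for idx in order[:remainder]:
        counts[idx] += 1
    return dict(zip(names, counts.tolist()))


def _observe(
    rng_err: np.random.Generator,
    true_mz: float,
    spec: SyntheticSpec,
) -> tuple[float, float]:
    """Apply systematic drift + random jitter; returns (observed, error ppm)."""
    jitter = float(rng_err.normal(0.0, spec.jitter_ppm)) if spec.jitter_ppm > 0 else 0.0
    err = spec.drift_a + spec.drift_b * true_mz + jitter
    return true_mz * (1.0 + err * 1e-6), err


def generate_sample(spec: SyntheticSpec) -> tuple[SamplePeakList, pd.DataFrame]:
    """Generate one peak list plus its ground-truth table.

    Ground truth has one row per generated peak: kind (compound,
    series, chain, spike, contaminant), true formula and class, true
    neutral mass and ionized m/z, the drawn ppm error, and series/chain/
    reference ids (-1 when not applicable).
    """
    rng = _streams(spec.seed)
    seen: set[str] = set()
    records: list[dict] = []

    def add_peak(kind: str, formula: Optional[MolecularFormula], true_mz: float, **ids) -> None:
        obs, err = _observe(rng["errors"], true_mz, spec)
        records.append(
            {
                "kind": kind,
                "formula": str(formula) if formula is not None else "",
                "compound_class": classify(formula) if formula is not None else "",
                "neutral_mass": formula.mass if formula is not None else float("nan"),
                "true_mz": true_mz,
                "observed_mz": obs,
                "error_ppm": err,
                "series_id": ids.get("series_id", -1),
                "chain_id": ids.get("chain_id", -1),
                "ref_id": ids.get("ref_id", -1),
            }
        )

    # background compounds per class
    for cls, count in _class_counts(spec).items():
        for _ in range(count):
            f = _sample_formula_in_class(rng["formulas"], cls, spec, seen)
            add_peak("compound", f, mz_from_neutral(f.mass, spec.species))

    # planted CH2 homologous ladders (fatty-acid-like backbones)
    ch2 = MolecularFormula.parse("CH2")
    for sid in range(spec.n_series):
        for _ in range(400):
            c0 = int(rng["series"].integers(8, 23))
            unsat = int(rng["series"].integers(1, 5))  # rings + double bonds - 1
            base = MolecularFormula(
                c=c0, h=max(2, 2 * c0 - 2 * unsat), o=int(rng["series"].integers(2, 8))
            )
            top = base + ch2 * (spec.series_length - 1)
            if (
                spec.mass_range[0] <= base.mass
                and top.mass <= spec.mass_range[1]
                and all(str(base + ch2 * k) not in seen for k in range(spec.series_length))
            ):
                break
        else:
            raise ValueError("could not place a CH2 series inside the mass range")
        for k in range(spec.series_length):
            f = base + ch2 * k
            seen.add(str(f))
            add_peak("series", f, mz_from_neutral(f.mass, spec.species), series_id=sid)

    # planted transformation chains
    if spec.n_chains:
        cat = {t.name: t for t in default_transformations()}
        steps = [cat[name] for name in spec.chain_transformations]
        for cid in range(spec.n_chains):
            for _ in range(200):
                c0 = int(rng["chains"].integers(10, 25))
                o0 = int(rng["chains"].integers(3, 9))
                base = MolecularFormula(c=c0, h=c0 - (c0 % 2), o=o0)
                seq = [
                    steps[int(rng["chains"].integers(0, len(steps)))]
                    for _ in range(spec.chain_length - 1)
                ]
                members = [base]
                for t in seq:
                    members.append(members[-1] + t.formula)
                if members[-1].mass <= spec.mass_range[1] and all(
                    str(m) not in seen for m in members
                ):
                    break
            else:
                raise ValueError("could not place a transformation chain in the mass range")
            for m in members:
                seen.add(str(m))
                add_peak("chain", m, mz_from_neutral(m.mass, spec.species), chain_id=cid)

    # reference spike-ins
    for rid, comp in enumerate(spec.spike_references):
        add_peak(
            "spike", comp.formula, mz_from_neutral(comp.neutral_mass, spec.species), ref_id=rid
        )

    # contaminant peaks with no CHONSP formula within 2 ppm of their neutral mass
    n_cont = int(round(spec.contaminant_fraction * spec.n_compounds))
    lo = mz_from_neutral(spec.mass_range[0], spec.species)
    hi = mz_from_neutral(spec.mass_range[1], spec.species)
    placed = 0
    while placed < n_cont:
        mz_c = float(rng["contaminants"].uniform(lo, hi))
        neutral = mz_c - spec.species.mass_shift
        if enumerate_candidates(neutral, tol_ppm=2.0, bounds=spec.bounds):
            continue
        add_peak("contaminant", None, mz_c)
        placed += 1

    truth = pd.DataFrame.from_records(records)
    n = len(truth)
    truth["intensity"] = np.exp(
        rng["intensity"].normal(spec.intensity_mu, spec.intensity_sigma, size=n)
    ).round(3)
    truth["sn"] = np.exp(rng["sn"].normal(spec.sn_mu, spec.sn_sigma, size=n)).round(3)
    truth = truth.sort_values("observed_mz", kind="mergesort").reset_index(drop=True)
    truth.insert(0, "peak_index", range(n))

    peaks = SamplePeakList(
        spec.sample_id,
        pd.DataFrame(
            {
                "mz": truth["observed_mz"].to_numpy(),
                "intensity": truth["intensity"].to_numpy(),
                "sn": truth["sn"].to_numpy(),
            }
        ),
    )
    return peaks, truth


# -- summary-table emulators ------------------------------------------------

DEFAULT_CLASS_TOTALS: dict[str, float] = {
    "Sugars": 3360.0,
    "Acids": 1010.0,
    "Amino Acids": 790.0,
    "Polyols": 256.0,
    "Amines": 156.0,
    "Cholines": 47.0,
}


def generate_concentration_table(
    seed: int = 0,
    class_totals_um: Optional[dict[str, float]] = None,
    metabolites_per_class: int = 5,
    floor_um: float = 1.0,
) -> pd.DataFrame:
    """Emulate an NMR quantitation table: log-normal concentrations per
    class rescaled so each class sums exactly to its target, floored at
    the ~1 uM detection limit."""
    totals = DEFAULT_CLASS_TOTALS if class_totals_um is None else class_totals_um
    rng = _streams(seed)["tables"]
    rows = []
    for cls in sorted(totals):
        target = float(totals[cls])
        if target <= 0 or metabolites_per_class == 0:
            continue
        raw = np.exp(rng.normal(0.0, 1.5, size=metabolites_per_class))
        conc = raw * target / raw.sum()
        # floor at the detection limit, absorbing the excess from the rest
        for _ in range(metabolites_per_class):
            low = conc < floor_um
            if not low.any() or low.all():
                break
            deficit = float((floor_um - conc[low]).sum())
            conc[low] = floor_um
            free = ~low
            conc[free] -= deficit * conc[free] / conc[free].sum()
        conc = np.maximum(conc, floor_um)
        for i, c in enumerate(conc):
            rows.append(
                {
                    "name": f"{cls.lower().replace(' ', '_')}_{i + 1}",
                    "formula": "",
                    "concentration_um": float(c),
                    "compound_class": cls,
                }
            )
    return pd.DataFrame(rows, columns=["name", "formula", "concentration_um", "compound_class"])


DEFAULT_LIPID_SUBCLASSES: tuple[tuple[str, str], ...] = (
    ("Sphingolipid", "Cer"),
    ("Sphingolipid", "HexCer"),
    ("Sphingolipid", "PE-Cer"),
    ("Sphingolipid", "MIPC"),
    ("Prenyl lipid", "CoQ"),
    ("Glycerophospholipid", "CL"),
    ("Glycerophospholipid", "PA"),
    ("Glycerophospholipid", "PC-lyso"),
    ("Glycerophospholipid", "PC"),
    ("Glycerophospholipid", "PE"),
    ("Glycerophospholipid", "PG"),
    ("Glycerophospholipid", "PI"),
    ("Glycerolipid", "DGDG"),
    ("Glycerolipid", "DGTS/A"),
    ("Glycerolipid", "SQDG"),
    ("Glycerolipid", "DG"),
    ("Glycerolipid", "TG"),
    ("Unknown", "Unknown_A"),
    ("Unknown", "Unknown_B"),
)


def generate_lipid_counts(
    seed: int = 0,
    total: int = 152,
    subclasses: Sequence[tuple[str, str]] = DEFAULT_LIPID_SUBCLASSES,
) -> pd.DataFrame:
    """Emulate a lipid identification tally: multinomial subclass counts
    with an embedded total row consistent by construction."""
    rng = _streams(seed)["tables"]
    k = len(subclasses)
    if total == 0 or k == 0:
        counts = np.zeros(k, dtype=int)
    else:
        counts = rng.multinomial(total, np.full(k, 1.0 / k))
    rows = [
        {"category": cat, "subclass": sub, "count": int(c)}
        for (cat, sub), c in zip(subclasses, counts)
    ]
    rows.append({"category": "", "subclass": "Total identifications", "count": int(counts.sum())})
    return pd.DataFrame(rows, columns=["category", "subclass", "count"])
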