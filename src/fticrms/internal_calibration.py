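"""Internal recalibration on CH2 homologous series.

Natural organic matter spectra contain long homologous series whose
members differ by exactly one CH2 unit (14.015650 Da).  Detecting those
ladders, anchoring each to a theoretical mass through a formula match on
its lowest-mass member, and regressing the observed ppm error against m/z
yields an internal calibration that removes systematic drift without any
external standard.

The calibration model is linear in m/z in ppm space:
``e(mz) = intercept + slope * mz``; corrected m/z = mz * (1 - e(mz) * 1e-6).
A linear model captures constant offset plus scale drift while staying
safe to fit from a handful of calibrants.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .chem_core import NEGATIVE, IonSpecies, MolecularFormula, neutral_from_mz, ppm_error
from .formula_assignment import DEFAULT_BOUNDS, ElementBounds, assign_mass
from .peaklist_io import SamplePeakList

log = logging.getLogger(__name__)

CH2 = MolecularFormula.parse("CH2")

__all__ = [
    "CH2",
    "HomologousSeries",
    "CalibrationModel",
    "find_series",
    "fit_calibration",
    "apply_calibration",
    "calibrate_sample",
]


@dataclass
class HomologousSeries:
    """A maximal chain of peaks spaced by one repeat unit (default CH2)."""

    mz: np.ndarray  # member m/z values, ascending
    repeat_unit: MolecularFormula = CH2

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        if len(self.mz) < 3:
            raise ValueError("a homologous series needs at least 3 members")

    def __len__(self) -> int:
        return len(self.mz)

    @property
    def kendrick_defect(self) -> float:
        """Kendrick mass defect of the series head for its repeat unit."""
        exact = self.repeat_unit.mass
        nominal = round(exact)
        km = self.mz[0] * nominal / exact
        return round(km) - km


def find_series(
    sample: SamplePeakList | Sequence[float],
    repeat_unit: MolecularFormula = CH2,
    tol_ppm: float = 1.0,
) -> list[HomologousSeries]:
    """Detect maximal homologous chains in an m/z-sorted peak list.

    Starting from each unconsumed peak in ascending order, the chain is
    extended to the nearest peak within ``tol_ppm`` (relative to the
    larger m/z) of the expected next rung.  A peak joins at most one
    chain; chains shorter than 3 are discarded.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    mz = sample.mz if isinstance(sample, SamplePeakList) else np.sort(np.asarray(sample, float))
    delta = repeat_unit.mass
    n = len(mz)
    used = np.zeros(n, dtype=bool)
    series: list[HomologousSeries] = []
    for i in range(n):
        if used[i]:
            continue
        chain = [i]
        cur = mz[i]
        while True:
            target = cur + delta
            tol_da = target * tol_ppm * 1e-6
            lo = np.searchsorted(mz, target - tol_da, side="left")
            hi = np.searchsorted(mz, target + tol_da, side="right")
            cand = [j for j in range(lo, hi) if not used[j]]
            if not cand:
                break
            j = min(cand, key=lambda k: abs(mz[k] - target))
            chain.append(j)
            cur = mz[j]
            used[j] = True
        if len(chain) >= 3:
            used[chain] = True
            series.append(HomologousSeries(mz[chain], repeat_unit))
    return series


@dataclass
class CalibrationModel:
    """Linear-in-m/z ppm error model plus fit diagnostics."""

    slope: float  # ppm per Da
    intercept: float  # ppm
    residual_rms_ppm: float = 0.0
    prefit_rms_ppm: float = 0.0
    n_calibrants: int = 0

    def error_ppm(self, mz: np.ndarray | float) -> np.ndarray | float:
        return self.intercept + self.slope * np.asarray(mz, dtype=float)

    @classmethod
    def identity(cls) -> "CalibrationModel":
        return cls(slope=0.0, intercept=0.0)


def fit_calibration(
    observed_mz: Sequence[float],
    reference_mz: Sequence[float],
) -> CalibrationModel:
    """Least-squares line through (m/z, ppm error) calibrant pairs.

    ``reference_mz`` are the theoretical masses of the same calibrant
    peaks.  Requires at least two calibrants at distinct m/z.
    """
    obs = np.asarray(observed_mz, dtype=float)
    ref = np.asarray(reference_mz, dtype=float)
    if obs.shape != ref.shape or obs.ndim != 1:
        raise ValueError("observed and reference m/z must be equal-length 1-D arrays")
    if len(obs) < 2:
        raise ValueError("at least two calibrants are required")
    if np.ptp(obs) == 0:
        raise ValueError("calibrant m/z values are all identical; fit is degenerate")
    err = (obs - ref) / ref * 1e6
    prefit = float(np.sqrt(np.mean(err**2)))
    slope, intercept = np.polyfit(obs, err, 1)
    resid = err - (intercept + slope * obs)
    return CalibrationModel(
        slope=float(slope),
        intercept=float(intercept),
        residual_rms_ppm=float(np.sqrt(np.mean(resid**2))),
        prefit_rms_ppm=prefit,
        n_calibrants=len(obs),
    )


def apply_calibration(sample: SamplePeakList, model: CalibrationModel) -> SamplePeakList:
    """Correct every m/z by its modeled ppm error; intensities/S-N unchanged."""
    df = sample.peaks.copy()
    err = model.error_ppm(df["mz"].to_numpy())
    df["mz"] = df["mz"].to_numpy() * (1.0 - np.asarray(err) * 1e-6)
    return SamplePeakList(sample.sample_id, df)


@dataclass
class CalibrationReport:
    model: CalibrationModel
    n_series: int
    n_anchored: int
    n_calibrants: int
    prefit_rms_ppm: float
    postfit_rms_ppm: float


def _anchor_calibrants(
    series: list[HomologousSeries],
    species: IonSpecies,
    anchor_tol_ppm: float,
    bounds: ElementBounds,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Theoretical ladder for each series via a formula match on its head."""
    obs_all: list[float] = []
    ref_all: list[float] = []
    n_anchored = 0
    delta = None
    for ser in series:
        delta = ser.repeat_unit.mass
        head = float(ser.mz[0])
        neutral = neutral_from_mz(head, species)
        best = assign_mass(neutral, tol_ppm=anchor_tol_ppm, bounds=bounds, mz=head)
        if best is None:
            continue
        n_anchored += 1
        theo_head = best.formula.mass + species.mass_shift
        for k, mz_k in enumerate(ser.mz):
            obs_all.append(float(mz_k))
            ref_all.append(theo_head + k * delta)
    return np.asarray(obs_all), np.asarray(ref_all), n_anchored


def calibrate_sample(
    sample: SamplePeakList,
    species: IonSpecies = NEGATIVE,
    repeat_unit: MolecularFormula = CH2,
    series_tol_ppm: float = 1.5,
    anchor_tol_ppm: float = 8.0,
    refine_tol_ppm: float = 1.0,
    bounds: ElementBounds = DEFAULT_BOUNDS,
) -> tuple[SamplePeakList, CalibrationReport]:
    """Full internal calibration of one sample.

    Two-pass bootstrap: series heads are first anchored inside a wide
    window (``anchor_tol_ppm``, sized to exceed any plausible uncorrected
    drift), outlier calibrants beyond 3 fitted-RMS are dropped, and after
    applying the provisional model the anchoring is repeated at
    ``refine_tol_ppm`` on corrected masses for the final fit.  Returns the
    corrected peak list and a report; if fewer than two calibrants are
    found the sample is returned unchanged under an identity model.
    """
    series = find_series(sample, repeat_unit, tol_ppm=series_tol_ppm)
    obs, ref, n_anchored = _anchor_calibrants(series, species, anchor_tol_ppm, bounds)
    if len(obs) < 2 or np.ptp(obs) == 0:
        log.warning(
            "sample %s: %d calibrant(s) found; skipping calibration", sample.sample_id, len(obs)
        )
        model = CalibrationModel.identity()
        return sample, CalibrationReport(model, len(series), n_anchored, len(obs), 0.0, 0.0)
    model1 = fit_calibration(obs, ref)
    # robust pass: drop calibrants with residuals beyond 3x fitted RMS
    err = (obs - ref) / ref * 1e6
    resid = err - model1.error_ppm(obs)
    cut = 3.0 * max(model1.residual_rms_ppm, 0.05)
    keep = np.abs(resid) <= cut
    if keep.sum() >= 2 and np.ptp(obs[keep]) > 0 and keep.sum() < len(obs):
        model1 = fit_calibration(obs[keep], ref[keep])

    corrected = apply_calibration(sample, model1)
    series2 = find_series(corrected, repeat_unit, tol_ppm=series_tol_ppm)
    obs2, ref2, n_anchored2 = _anchor_calibrants(series2, species, refine_tol_ppm, bounds)
    if len(obs2) >= 2 and np.ptp(obs2) > 0:
        model2 = fit_calibration(obs2, ref2)
        final = apply_calibration(corrected, model2)
        # compose: e_total ~ e1 + e2 (second-order cross terms negligible at ppm scale)
        total = CalibrationModel(
            slope=model1.slope + model2.slope,
            intercept=model1.intercept + model2.intercept,
            residual_rms_ppm=model2.residual_rms_ppm,
            prefit_rms_ppm=model1.prefit_rms_ppm,
            n_calibrants=model2.n_calibrants,
        )
        report = CalibrationReport(
            total,
            n_series=len(series2),
            n_anchored=n_anchored2,
            n_calibrants=len(obs2),
            prefit_rms_ppm=model1.prefit_rms_ppm,
            postfit_rms_ppm=model2.residual_rms_ppm,
        )
        return final, report
    report = CalibrationReport(
        model1,
        n_series=len(series),
        n_anchored=n_anchored,
        n_calibrants=int(keep.sum()),
        prefit_rms_ppm=model1.prefit_rms_ppm,
        postfit_rms_ppm=model1.residual_rms_ppm,
    )
    return corrected, report
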