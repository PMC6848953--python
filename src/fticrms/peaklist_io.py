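"""Per-sample peak lists: reading, noise filtering, and cross-sample alignment.

A peak list is the output of instrument-side peak picking: one row per
detected ion with m/z, absolute intensity and signal-to-noise ratio.
Filtering applies the acquisition thresholds (S/N strictly above 7,
intensity at least 100 by default).  Alignment clusters m/z values across
samples by greedy single linkage at a ppm tolerance so one consensus mass
receives consistent formula assignments in every sample.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

PEAK_COLUMNS = ("mz", "intensity", "sn")

#: Acquired m/z window; peaks outside it are discarded during filtering.
DEFAULT_MZ_RANGE = (100.0, 1200.0)


@dataclass
class SamplePeakList:
    """One sample's peaks, sorted by strictly increasing m/z."""

    sample_id: str
    peaks: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=PEAK_COLUMNS))

    def __post_init__(self) -> None:
        missing = set(PEAK_COLUMNS) - set(self.peaks.columns)
        if missing:
            raise ValueError(f"peak table missing columns {sorted(missing)}")
        self.peaks = (
            self.peaks.loc[:, list(PEAK_COLUMNS)]
            .astype(float)
            .sort_values("mz", kind="mergesort")
            .reset_index(drop=True)
        )

    def __len__(self) -> int:
        return len(self.peaks)

    @property
    def mz(self) -> np.ndarray:
        return self.peaks["mz"].to_numpy()

    @property
    def intensity(self) -> np.ndarray:
        return self.peaks["intensity"].to_numpy()

    @property
    def sn(self) -> np.ndarray:
        return self.peaks["sn"].to_numpy()

    @classmethod
    def from_arrays(
        cls,
        sample_id: str,
        mz: Sequence[float],
        intensity: Sequence[float] | None = None,
        sn: Sequence[float] | None = None,
    ) -> "SamplePeakList":
        n = len(mz)
        return cls(
            sample_id,
            pd.DataFrame(
                {
                    "mz": np.asarray(mz, dtype=float),
                    "intensity": np.ones(n) * 1000.0
                    if intensity is None
                    else np.asarray(intensity, dtype=float),
                    "sn": np.ones(n) * 10.0 if sn is None else np.asarray(sn, dtype=float),
                }
            ),
        )

    def write(self, path: str | os.PathLike) -> None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
        self.peaks.to_csv(path, sep=sep, index=False, float_format="%.8f")


def _sep_for(path: str | os.PathLike, dialect: str | None) -> str:
    if dialect == "tsv":
        return "\t"
    if dialect == "csv":
        return ","
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def read_peaklist(
    path: str | os.PathLike,
    sample_id: str | None = None,
    dialect: str | None = None,
) -> SamplePeakList:
    """Read a delimited peak list with header columns mz, intensity, sn.

    Malformed rows (non-numeric fields, negative values) are dropped and
    reported through the module logger with their line numbers; missing
    columns raise.
    """
    sep = _sep_for(path, dialect)
    raw = pd.read_csv(path, sep=sep, dtype=str, comment="#")
    raw.columns = [c.strip().lower() for c in raw.columns]
    missing = set(PEAK_COLUMNS) - set(raw.columns)
    if missing:
        raise ValueError(f"{path}: missing required column(s) {sorted(missing)}")
    numeric = raw.loc[:, list(PEAK_COLUMNS)].apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().any(axis=1) | (numeric < 0).any(axis=1) | (numeric["mz"] <= 0)
    if bad.any():
        # +2: one for the header line, one for 1-based numbering.
        lines = [int(i) + 2 for i in numeric.index[bad]]
        log.warning("%s: rejected %d malformed row(s) at line(s) %s", path, len(lines), lines)
    clean = numeric.loc[~bad]
    if clean.empty:
        log.warning("%s: no valid peaks parsed", path)
    sid = sample_id if sample_id is not None else os.path.splitext(os.path.basename(path))[0]
    return SamplePeakList(sid, clean)


def filter_peaks(
    sample: SamplePeakList,
    sn_min: float = 7.0,
    intensity_min: float = 100.0,
    mz_range: tuple[float, float] | None = DEFAULT_MZ_RANGE,
) -> SamplePeakList:
    """Apply peak-picking thresholds: S/N strictly above ``sn_min``,
    intensity at least ``intensity_min``, m/z inside the acquired window.

    Idempotent; order-preserving; the output is never longer than the input.
    """
    if sn_min < 0 or intensity_min < 0:
        raise ValueError("thresholds must be non-negative")
    df = sample.peaks
    keep = (df["sn"] > sn_min) & (df["intensity"] >= intensity_min)
    if mz_range is not None:
        keep &= (df["mz"] >= mz_range[0]) & (df["mz"] <= mz_range[1])
    return SamplePeakList(sample.sample_id, df.loc[keep])


@dataclass
class AlignedMatrix:
    """Consensus m/z rows x sample columns; NaN marks absence.

    ``intensity`` holds per-sample intensities at each consensus mass;
    ``sample_mz`` the member m/z each sample contributed; ``conflicts``
    counts clusters where one sample offered more than one peak (the peak
    nearest the consensus wins).
    """

    intensity: pd.DataFrame
    sample_mz: pd.DataFrame
    conflicts: int = 0

    @property
    def consensus_mz(self) -> np.ndarray:
        return self.intensity.index.to_numpy()

    def write(self, path: str | os.PathLike) -> None:
        out = self.intensity.copy()
        out.insert(0, "consensus_mz", out.index)
        out.to_csv(path, index=False, float_format="%.8f")


def align_samples(
    samples: Iterable[SamplePeakList],
    tol_ppm: float = 1.0,
) -> AlignedMatrix:
    """Align peak lists across samples by single-linkage m/z clustering.

    The merged m/z list is sorted and split wherever the gap between
    consecutive peaks exceeds ``tol_ppm`` of the larger m/z; each chained
    run becomes one cluster.  The consensus m/z is the intensity-weighted
    mean of cluster members.  When a sample contributes two peaks to one
    cluster, the peak nearest the consensus is kept and the conflict is
    logged.
    """
    samples = list(samples)
    if not samples:
        raise ValueError("at least one sample is required")
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    frames = []
    for s in samples:
        df = s.peaks.copy()
        df["sample_id"] = s.sample_id
        frames.append(df)
    merged = pd.concat(frames, ignore_index=True).sort_values("mz", kind="mergesort")
    mz = merged["mz"].to_numpy()
    if len(mz) == 0:
        empty = pd.DataFrame(columns=[s.sample_id for s in samples])
        return AlignedMatrix(empty, empty.copy())
    gaps = np.diff(mz)
    new_cluster = gaps > (mz[1:] * tol_ppm * 1e-6)
    cluster_id = np.concatenate([[0], np.cumsum(new_cluster)])
    merged = merged.assign(cluster=cluster_id)

    sample_ids = [s.sample_id for s in samples]
    conflicts = 0
    rows_int: dict[float, dict[str, float]] = {}
    rows_mz: dict[float, dict[str, float]] = {}
    for _, grp in merged.groupby("cluster", sort=True):
        w = grp["intensity"].to_numpy()
        m = grp["mz"].to_numpy()
        consensus = float(np.average(m, weights=w) if w.sum() > 0 else m.mean())
        irow: dict[str, float] = {}
        mrow: dict[str, float] = {}
        for sid, sub in grp.groupby("sample_id"):
            if len(sub) > 1:
                conflicts += 1
                log.warning(
                    "alignment conflict: sample %s has %d peaks in cluster at %.6f",
                    sid,
                    len(sub),
                    consensus,
                )
                sub = sub.iloc[[int(np.argmin(np.abs(sub["mz"].to_numpy() - consensus)))]]
            irow[sid] = float(sub["intensity"].iloc[0])
            mrow[sid] = float(sub["mz"].iloc[0])
        rows_int[consensus] = irow
        rows_mz[consensus] = mrow

    intensity = pd.DataFrame.from_dict(rows_int, orient="index", columns=sample_ids)
    sample_mz = pd.DataFrame.from_dict(rows_mz, orient="index", columns=sample_ids)
    intensity = intensity.sort_index()
    sample_mz = sample_mz.sort_index()
    intensity.index.name = "consensus_mz"
    sample_mz.index.name = "consensus_mz"
    return AlignedMatrix(intensity, sample_mz, conflicts=conflicts)
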