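"""End-to-end orchestration: filter -> calibrate -> align -> assign ->
classify -> network/neighbors -> reference match -> PCA -> summaries.

Stages run in a fixed order with explicit file hand-offs (every stage's
inputs and outputs are delimited text in the output directory), stage
toggles, and a resolved-config echo so any run can be reproduced
byte-for-byte from its own output directory.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import (
    class_pca,
    formula_assignment,
    internal_calibration,
    peaklist_io,
    reference_matching,
    table_summaries,
    transformation_network,
    vankrevelen,
)
from .chem_core import NEGATIVE, POSITIVE, IonSpecies

log = logging.getLogger(__name__)

STAGES = (
    "filter",
    "calibrate",
    "align",
    "assign",
    "classify",
    "network",
    "neighbors",
    "match",
    "pca",
    "summarize",
)


@dataclass
class SampleInput:
    sample_id: str
    path: str
    group: str = ""


@dataclass
class PipelineConfig:
    """Everything a run needs; unknown keys in a config file are rejected."""

    samples: list[SampleInput] = field(default_factory=list)
    output_dir: str = "fticrms_out"
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    ion_mode: str = "neg"
    sn_min: float = 7.0
    intensity_min: float = 100.0
    mz_min: float = 100.0
    mz_max: float = 1200.0
    align_tol_ppm: float = 1.0
    assign_tol_ppm: float = 1.0
    bounds: str = "C:1-100,H:0-200,O:0-50,N:0-5,S:0-2,P:0-2"
    network_tol_da: float = 0.001
    transformations_file: Optional[str] = None
    reference_file: Optional[str] = None
    match_tol_ppm: float = 1.0
    pca_components: int = 2
    concentration_table: Optional[str] = None
    lipid_count_table: Optional[str] = None
    log_level: str = "INFO"
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ValueError(f"unknown stage(s) {unknown}; valid: {list(STAGES)}")
        if self.ion_mode not in ("neg", "pos"):
            raise ValueError("ion_mode must be 'neg' or 'pos'")

    @property
    def species(self) -> IonSpecies:
        return NEGATIVE if self.ion_mode == "neg" else POSITIVE

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s) {sorted(unknown)}")
        raw = dict(raw)
        raw["samples"] = [
            s if isinstance(s, SampleInput) else SampleInput(**s) for s in raw.get("samples", [])
        ]
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order; returns the run report.

    All inputs are validated before the first stage runs.  Outputs are
    written under ``config.output_dir`` with stable filenames; the report
    carries per-stage counts (peaks kept, formulas assigned, unknowns,
    edges, neighbors, matches) and is also written as ``report.json``
    beside a ``resolved_config.yaml`` echo.
    """
    t0 = time.time()
    for s in config.samples:
        if not os.path.exists(s.path):
            raise FileNotFoundError(f"input peak list not found: {s.path}")
    for attr in ("transformations_file", "reference_file", "concentration_table", "lipid_count_table"):
        p = getattr(config, attr)
        if p is not None and not os.path.exists(p):
            raise FileNotFoundError(f"{attr}: {p}")

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "resolved_config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)

    enabled = set(config.stages)
    report: dict = {"stages": {}, "samples": [s.sample_id for s in config.samples]}
    bounds = formula_assignment.ElementBounds.parse(config.bounds)

    samples = [
        peaklist_io.read_peaklist(s.path, sample_id=s.sample_id) for s in config.samples
    ]
    groups = {s.sample_id: (s.group or "ungrouped") for s in config.samples}

    if "filter" in enabled:
        kept = {}
        filtered = []
        for smp in samples:
            out = peaklist_io.filter_peaks(
                smp, config.sn_min, config.intensity_min, (config.mz_min, config.mz_max)
            )
            out.write(outdir / f"{smp.sample_id}.filtered.csv")
            kept[smp.sample_id] = len(out)
            filtered.append(out)
        samples = filtered
        report["stages"]["filter"] = {"peaks_kept": kept}

    if "calibrate" in enabled:
        stats = {}
        calibrated = []
        for smp in samples:
            out, rep = internal_calibration.calibrate_sample(smp, species=config.species)
            calibrated.append(out)
            stats[smp.sample_id] = {
                "series": rep.n_series,
                "calibrants": rep.n_calibrants,
                "prefit_rms_ppm": round(rep.prefit_rms_ppm, 4),
                "postfit_rms_ppm": round(rep.postfit_rms_ppm, 4),
            }
            out.write(outdir / f"{smp.sample_id}.calibrated.csv")
        samples = calibrated
        report["stages"]["calibrate"] = stats

    if "align" in enabled and len(samples) > 1:
        matrix = peaklist_io.align_samples(samples, tol_ppm=config.align_tol_ppm)
        matrix.write(outdir / "aligned_matrix.csv")
        report["stages"]["align"] = {
            "consensus_masses": len(matrix.intensity),
            "conflicts": matrix.conflicts,
        }

    assignments: dict[str, pd.DataFrame] = {}
    if "assign" in enabled:
        stats = {}
        for smp in samples:
            table = formula_assignment.assign_sample(
                smp, species=config.species, tol_ppm=config.assign_tol_ppm, bounds=bounds
            )
            assignments[smp.sample_id] = table
            stats[smp.sample_id] = {
                "assigned": int((table["status"] == "assigned").sum()),
                "unknown": int((table["status"] == "unknown").sum()),
            }
        report["stages"]["assign"] = stats

    abundances: dict[str, dict[str, float]] = {}
    if "classify" in enabled and assignments:
        for sid, table in assignments.items():
            table = vankrevelen.classify_table(table)
            assignments[sid] = table
            table.to_csv(outdir / f"{sid}.assignments.csv", index=False, float_format="%.8f")
            if (table["status"] == "assigned").any():
                abundances[sid] = vankrevelen.class_abundance(table)
        if abundances:
            vankrevelen.abundance_matrix(abundances).to_csv(outdir / "class_abundance.csv")
        report["stages"]["classify"] = {
            sid: {k: round(v, 4) for k, v in ab.items()} for sid, ab in abundances.items()
        }
    elif assignments:
        for sid, table in assignments.items():
            table.to_csv(outdir / f"{sid}.assignments.csv", index=False, float_format="%.8f")

    transformations = (
        transformation_network.load_transformations(config.transformations_file)
        if config.transformations_file
        else transformation_network.default_transformations()
    )
    reference = (
        reference_matching.load_reference(config.reference_file)
        if config.reference_file
        else reference_matching.load_antimicrobial_reference()
    )

    networks: dict[str, object] = {}
    if "network" in enabled:
        stats = {}
        for smp in samples:
            g = transformation_network.build_network(
                smp.mz, transformations, tol_da=config.network_tol_da
            )
            if smp.sample_id in assignments:
                transformation_network.annotate_network(g, assignments[smp.sample_id])
            networks[smp.sample_id] = g
            transformation_network.edge_table(g).to_csv(
                outdir / f"{smp.sample_id}.edges.csv", index=False, float_format="%.8f"
            )
            stats[smp.sample_id] = {"nodes": g.number_of_nodes(), "edges": g.number_of_edges()}
        report["stages"]["network"] = stats

    if "neighbors" in enabled and networks:
        stats = {}
        ref_mz = reference_matching.distinct_mz(reference, config.species)
        for sid, g in networks.items():
            smp = next(s for s in samples if s.sample_id == sid)
            seeds = []
            for theo in ref_mz["theoretical_mz"]:
                tol_da = theo * config.match_tol_ppm * 1e-6
                near = smp.mz[(smp.mz >= theo - tol_da) & (smp.mz <= theo + tol_da)]
                seeds.extend(float(v) for v in near)
            sub, n_nb = transformation_network.first_neighbors(g, seeds)
            transformation_network.node_table(sub).to_csv(
                outdir / f"{sid}.neighbors.csv", index=False, float_format="%.8f"
            )
            transformation_network.write_graphml(sub, outdir / f"{sid}.neighbors.graphml")
            stats[sid] = {"seeds_present": len(set(seeds) & set(g.nodes)), "neighbors": n_nb}
        report["stages"]["neighbors"] = stats

    if "match" in enabled:
        stats = {}
        for smp in samples:
            matches = reference_matching.match_peaks(
                smp, reference, config.species, tol_ppm=config.match_tol_ppm
            )
            matches.to_csv(outdir / f"{smp.sample_id}.matches.csv", index=False, float_format="%.8f")
            stats[smp.sample_id] = {
                "matched_refs": int((matches["status"] == "matched").sum()),
                "unmatched_refs": int((matches["status"] == "unmatched").sum()),
            }
        report["stages"]["match"] = stats

    if "pca" in enabled and len(abundances) >= 2:
        matrix = vankrevelen.abundance_matrix(abundances)
        result = class_pca.pca(matrix, n_components=min(config.pca_components, len(matrix) - 1, matrix.shape[1]))
        result.scores.to_csv(outdir / "pca_scores.csv")
        result.loadings.to_csv(outdir / "pca_loadings.csv")
        pd.Series(result.explained_variance_ratio, name="explained_variance_ratio").to_csv(
            outdir / "pca_variance.csv", index_label="component"
        )
        stage = {"explained_variance_ratio": [round(float(v), 4) for v in result.explained_variance_ratio]}
        if len(set(groups.values())) >= 2:
            dist = class_pca.group_distances(result, {k: groups[k] for k in matrix.index})
            dist.to_csv(outdir / "group_distances.csv", index=False)
            stage["closest_groups"] = [
                str(dist.iloc[0]["group_a"]),
                str(dist.iloc[0]["group_b"]),
            ]
        report["stages"]["pca"] = stage

    if "summarize" in enabled:
        stage = {}
        conc = (
            table_summaries.load_concentration_table(config.concentration_table)
            if config.concentration_table
            else table_summaries.load_metabolite_concentrations()
        )
        totals = table_summaries.class_totals(conc)
        totals.to_csv(outdir / "class_totals.csv")
        stage["class_totals_um"] = {
            str(k): float(v) for k, v in totals["total_um_3sf"].items()
        }
        lip = (
            table_summaries.load_count_table(config.lipid_count_table)
            if config.lipid_count_table
            else table_summaries.load_lipid_subclass_counts()
        )
        total, consistent = table_summaries.subclass_total(lip)
        stage["lipid_total"] = total
        stage["lipid_total_consistent"] = consistent
        counts = table_summaries.load_platform_counts()
        stage["platform_total"] = table_summaries.platform_total(counts)
        report["stages"]["summarize"] = stage

    report["runtime_s"] = round(time.time() - t0, 3)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
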