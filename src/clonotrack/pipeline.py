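"""End-to-end orchestration: simulate -> genex -> clonal -> track -> report.

All randomness flows from one root seed, expanded per stage, so stages can be
re-run independently yet reproducibly.  The run report collects parameter
values, row counts per stage and every summary statistic the modules compute
(tracking-rate mean +/- sd, publicity category counts per subset and cohort,
exclusivity set sizes, convergence-frequency correlations, marker-gene
counts); it is emitted as TSV blocks plus a human-readable text summary and
is byte-identical across re-runs with the same seed and config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import assays, clonal, genex, trackback
from .repertoire_io import SUBSETS
from .synthetic_data import SimConfig, SimResult, simulate_all, write_sim

logger = logging.getLogger(__name__)

STAGES = ("simulate", "genex", "clonal", "track", "assays")


@dataclass
class RunConfig:
    """Pipeline parameters; every module knob in one place."""

    seed: int = 0
    outdir: Optional[str] = None
    stages: tuple[str, ...] = STAGES
    sim: SimConfig = None  # derived from seed when not given
    alpha: float = 0.05
    logfc_threshold: float = 0.25
    n_pcs: int = 10
    resolution: float = 1.0
    n_neighbors: int = 20
    expansion_min_size: int = 2
    strict_v: bool = False
    correlation_per_repertoire: bool = False

    def __post_init__(self):
        if self.sim is None:
            self.sim = SimConfig(seed=self.seed)
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim_raw = raw.pop("sim", None)
        cfg = cls(**raw)
        if sim_raw:
            cfg.sim = SimConfig(seed=cfg.seed, **sim_raw)
        return cfg


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the enabled stages in dependency order and build the report."""
    report: dict = {
        "params": {
            "seed": cfg.seed, "alpha": cfg.alpha,
            "logfc_threshold": cfg.logfc_threshold, "n_pcs": cfg.n_pcs,
            "resolution": cfg.resolution,
            "expansion_min_size": cfg.expansion_min_size,
            "strict_v": cfg.strict_v, "stages": list(cfg.stages),
        }
    }
    if "simulate" not in cfg.stages:
        raise ValueError("pipeline currently starts from the simulate stage")
    result = simulate_all(cfg.sim)
    report["simulate"] = {
        "n_repertoires": result.reps.subset_counts(),
        "n_repertoires_total": len(result.reps),
        "n_cells": len(result.cells),
        "n_planted_clonotypes": len(result.manifest.clonotypes),
    }
    if cfg.outdir:
        write_sim(result, cfg.outdir)
        report["simulate"]["outdir"] = str(cfg.outdir)
        report["simulate"]["checksums"] = _input_checksums(cfg.outdir)

    if "genex" in cfg.stages:
        report["genex"] = _run_genex(cfg, result)
    if "clonal" in cfg.stages:
        report["clonal"] = _run_clonal(cfg, result)
    if "track" in cfg.stages:
        report["track"] = _run_track(cfg, result)
    if "assays" in cfg.stages:
        report["assays"] = _run_assays(cfg, result)
    return report


def _input_checksums(outdir) -> dict[str, str]:
    out = {}
    for f in sorted(Path(outdir).rglob("*.tsv")):
        out[str(f.relative_to(outdir))] = hashlib.sha256(f.read_bytes()).hexdigest()[:16]
    return out


def _run_genex(cfg: RunConfig, result: SimResult) -> dict:
    expr = genex.preprocess_ct(result.ct)
    labels = genex.cluster_cells(expr, n_pcs=cfg.n_pcs, resolution=cfg.resolution,
                                 seed=cfg.seed, n_neighbors=min(cfg.n_neighbors,
                                                                expr.et.shape[0] - 1))
    expr = expr.with_clusters(labels)
    results = genex.hurdle_test_all(expr, alpha=cfg.alpha,
                                    logfc_threshold=cfg.logfc_threshold)
    markers = [r for r in results if r.is_marker]
    composition = genex.cluster_composition_test(expr)
    return {
        "n_cells_in": len(result.ct.cell_meta),
        "n_cells_kept": expr.et.shape[0],
        "n_clusters": int(labels.nunique()),
        "n_tests": len(results),
        "n_markers": len(markers),
        "markers_per_cluster": {
            int(c): sum(1 for r in markers if r.cluster == c)
            for c in sorted({r.cluster for r in results})
        },
        "composition_min_p_adj": min(r.p_adj for r in composition),
        "cluster_labels": {str(k): int(v) for k, v in labels.items()},
    }


def _run_clonal(cfg: RunConfig, result: SimResult) -> dict:
    out = {}
    for level in clonal.MATCH_LEVELS:
        groups = clonal.find_expansions(result.cells, level=level,
                                        min_size=cfg.expansion_min_size)
        span = clonal.expansion_cluster_span(groups)
        out[level] = {
            "n_groups": span.n_groups,
            "n_cells_in_groups": sum(g.size for g in groups),
            "fraction_single_cluster": span.fraction_single_cluster,
        }
    return out


def _run_track(cfg: RunConfig, result: SimResult) -> dict:
    cells, reps = result.cells, result.reps
    out: dict = {}
    for level in ("nt", "aa"):
        rate = trackback.tracking_rate(cells, reps, level)
        out[f"tracking_rate_{level}"] = {
            "mean_pct": rate.mean, "sd_pct": rate.sd,
            "per_donor": {k: round(v, 6) for k, v in sorted(rate.per_donor.items())},
        }
    hits_aa = trackback.track_all(cells, reps, "aa", strict_v=cfg.strict_v)
    out["publicity"] = {}
    for subset in SUBSETS:
        recs = trackback.publicity_records(hits_aa, subset)
        counts = {c: 0 for c in trackback.PUBLICITY_CATEGORIES}
        for r in recs:
            counts[r.category] += 1
        out["publicity"][subset] = counts
    out["exclusivity"] = {}
    for subset in ("TN", "CM"):
        ex = trackback.exclusivity_sets(hits_aa, reps, subset)
        out["exclusivity"][subset] = {"hd_only": len(ex.hd_only),
                                      "t1d_only": len(ex.t1d_only)}
    out["correlation"] = {}
    for subset in ("TN", "CM"):
        try:
            corr = trackback.convergence_frequency_correlation(
                hits_aa, subset, per_repertoire=cfg.correlation_per_repertoire)
            out["correlation"][subset] = {"rho": corr.rho, "p": corr.p_value,
                                          "n": corr.n}
        except ValueError:
            out["correlation"][subset] = {"rho": None, "p": None, "n": 0}
    ratios = trackback.treg_cm_ratio(cells, reps)
    out["treg_cm_ratio"] = {
        "n": len(ratios),
        "median": float(ratios["ratio"].median()) if len(ratios) else None,
    }
    return out


def _run_assays(cfg: RunConfig, result: SimResult) -> dict:
    classes = {}
    for donor, grp in result.elispot.groupby("donor_id"):
        res = {}
        for _, row in grp.iterrows():
            m = assays.ElispotMeasurement(
                donor_id=donor, cytokine=row["cytokine"],
                spots_antigen=(row["antigen_1"], row["antigen_2"], row["antigen_3"]),
                spots_diluent=(row["diluent_1"], row["diluent_2"], row["diluent_3"]),
            )
            res[row["cytokine"]] = assays.stimulation_index(m)
        classes[donor] = assays.classify_elispot_response(res["IFNg"], res["IL10"])
    class_counts: dict[str, int] = {}
    for c in classes.values():
        class_counts[c] = class_counts.get(c, 0) + 1
    # phenotype gating on the index-sort intensities
    m = result.markers
    gated = []
    for _, row in m.iterrows():
        label = assays.gate_phenotype(
            assays.CellMarkers(CD45RO=row["CD45RO"], CD27=row["CD27"],
                               CD95=row["CD95"]),
            assays.GateThresholds(CD45RO=row["gate_CD45RO"],
                                  CD27=row["gate_CD27"], CD95=row["gate_CD95"]),
        )
        gated.append((row["donor_id"], label))
    gdf = pd.DataFrame(gated, columns=["donor_id", "phenotype"])
    dists = {d: assays.phenotype_distribution(list(grp["phenotype"]), d)
             for d, grp in gdf.groupby("donor_id")}
    return {
        "elispot_classes": dict(sorted(class_counts.items())),
        "phenotype_fraction_mean": {
            p: float(np.mean([dist[p] for dist in dists.values()]))
            for p in ("TN", "CM", "EM", "NTEM", "Tscm")
        },
    }


# ---------------------------------------------------------------------------
# Report serialisation
# ---------------------------------------------------------------------------

def report_to_text(report: dict) -> str:
    """Deterministic human-readable summary of a run report."""
    return json.dumps(report, sort_keys=True, indent=2, default=_json_default) + "\n"


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(f"not serialisable: {type(o)}")


def write_report(report: dict, path) -> None:
    Path(path).write_text(report_to_text(report))
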