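"""End-to-end orchestration: simulate (or load) a campaign and run every stage.

``run_pipeline`` produces, in an output directory: ``raw.tsv``, ``truth.tsv``
and ``annotation.gmt`` (demo/simulation mode), ``qc.tsv``, ``norm.tsv``,
``hits.tsv``, ``groups.tsv``, ``dissection.tsv``, ``edges.tsv``,
``enrich.tsv`` and a ``manifest.json`` echoing the configuration, package
versions and the seed. Runs are deterministic for a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .classify import build_cross_screen_profiles, classify_2d_dichotomy, classify_four_groups, group_sizes
from .dissect import dissect
from .enrich import gsea_table, hypergeometric_enrichment
from .errors import ConfigError
from .hits import HitThresholds, call_hits
from .network import build_similarity_network
from .normalize import normalize_screen, qc_report
from .screen_io import (
    invert_gene_sets,
    read_gmt,
    read_raw_screen,
    write_edge_list,
    write_gmt,
    write_normalized_screen,
    write_raw_screen,
    write_result_table,
    write_truth_table,
)
from .simulate import SimulationConfig, assign_effect_classes, simulate_annotation, simulate_campaign

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Configuration for a full pipeline run.

    Either ``raw_path`` points at an existing raw screen table, or
    ``simulation`` configures a simulated campaign (the demo mode). A seed is
    mandatory; it overrides the simulation seed and drives the enrichment
    permutations.
    """

    seed: int = 0
    raw_path: str | None = None
    gmt_path: str | None = None
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    thresholds: HitThresholds = field(default_factory=HitThresholds)
    normalize_center: str = "mean"
    network_min_score: float = 0.2
    per_cell_up_threshold: float = 0.5
    gsea_weight: float = 1.0
    gsea_permutations: int = 1000

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        sim = data.pop("simulation", {})
        thresholds = data.pop("thresholds", {})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown pipeline config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.simulation = sim if isinstance(sim, SimulationConfig) else SimulationConfig.from_dict(sim)
        cfg.thresholds = (
            thresholds if isinstance(thresholds, HitThresholds) else HitThresholds(**thresholds)
        )
        cfg.simulation.seed = cfg.seed
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as handle:
            return cls.from_dict(yaml.safe_load(handle) or {})

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        return out


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run every stage and write the artifact directory; returns a summary.

    The summary dict carries the in-memory products (hit tables, group
    counts, dissection table, ...) so callers can inspect results without
    re-reading the TSVs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = config.simulation
    sim.seed = config.seed

    truth = None
    if config.raw_path is None:
        truth = assign_effect_classes(sim)
        raw = simulate_campaign(sim, truth)
        annotation = (
            read_gmt(config.gmt_path)
            if config.gmt_path
            else simulate_annotation(truth, sim)
        )
        write_raw_screen(raw, out / "raw.tsv")
        write_truth_table(truth, out / "truth.tsv")
        write_gmt(annotation, out / "annotation.gmt")
    else:
        raw = read_raw_screen(config.raw_path)
        if not config.gmt_path:
            raise ConfigError("gmt_path is required when analyzing an external raw screen")
        annotation = read_gmt(config.gmt_path)

    qc = qc_report(raw)
    qc.to_csv(out / "qc.tsv", sep="\t", index=False)

    norm = normalize_screen(raw, center=config.normalize_center)
    write_normalized_screen(norm, out / "norm.tsv")

    hits = call_hits(norm, config.thresholds)
    write_result_table(hits, out / "hits.tsv")

    hits_2d = hits[hits["readout"] == "count2d"]
    hits_3d = hits[hits["readout"] == "sphere3d"]
    groups = classify_four_groups(hits_2d, hits_3d)
    profiles = build_cross_screen_profiles([hits])
    groups["dichotomy_2d"] = classify_2d_dichotomy(profiles).reindex(groups.index)
    groups.reset_index().to_csv(out / "groups.tsv", sep="\t", index=False)
    sizes = group_sizes(groups)

    hits_viab = hits[hits["readout"] == "viability2d"]
    dissection = None
    if len(hits_viab):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dissection = dissect(
                norm, norm, hits_2d, hits_viab,
                thresholds=config.thresholds,
                per_cell_up_threshold=config.per_cell_up_threshold,
            )
        dissection.to_csv(out / "dissection.tsv", sep="\t", index=False)

    hit_genes = sorted(groups.index[groups["group"] != "none"])
    gene_terms = invert_gene_sets(annotation)
    edges = build_similarity_network(hit_genes, gene_terms, min_score=config.network_min_score)
    write_edge_list(edges, out / "edges.tsv")

    universe = sorted(set(hits["gene_id"]))
    ora = hypergeometric_enrichment(set(hit_genes), universe, annotation)
    ora["mode"] = "ora"
    enrich_frames = [ora]
    if dissection is not None:
        first_line = dissection["cell_line"].iloc[0]
        ranking = (
            dissection[dissection["cell_line"] == first_line]
            .set_index("gene_id")["log2fc_viability_per_cell"]
            .dropna()
        )
        gsea = gsea_table(
            ranking,
            annotation,
            weight=config.gsea_weight,
            n_permutations=config.gsea_permutations,
            seed=config.seed,
        )
        if len(gsea):
            gsea["mode"] = "gsea"
            enrich_frames.append(gsea)
    enrichment = pd.concat(enrich_frames, ignore_index=True)
    enrichment.to_csv(out / "enrich.tsv", sep="\t", index=False)

    manifest = {
        "package": "sirnascreen",
        "version": __version__,
        "seed": config.seed,
        "config": _jsonable(config.to_dict()),
        "artifacts": sorted(p.name for p in out.iterdir() if p.suffix in (".tsv", ".gmt")),
        "group_sizes": sizes,
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True)

    return {
        "raw": raw,
        "truth": truth,
        "annotation": annotation,
        "qc": qc,
        "norm": norm,
        "hits": hits,
        "groups": groups,
        "group_sizes": sizes,
        "dissection": dissection,
        "edges": edges,
        "enrichment": enrichment,
        "manifest": manifest,
    }


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    return obj
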