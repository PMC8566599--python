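"""End-to-end orchestration: nodes -> cohort -> connectivity -> metrics -> inference.

A run is driven by a :class:`RunConfig` (round-trippable to YAML).  It
either simulates a self-contained synthetic cohort or reads per-subject
time-series TSVs plus a covariate CSV, then writes per-subject Fisher-z
matrices and graph metrics, group-comparison tables for edges, nodes and
global metrics under three covariate sets (base; base + mean FC;
base + IQ), the hub-ranking table, lobe-pair percentages of significant
edges, and a JSON run report.  A rerun from the same config and seed
reproduces every output byte for byte: all randomness flows from the
single global seed through fixed per-stage offsets.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import atlas
from .connectivity import FisherZConnectivity, aggregate_merged_series
from .inference import (
    BASE_COVARIATES,
    DesignSpec,
    classify_edges,
    edgewise_comparison,
    global_comparison,
    hub_ranking,
    nodal_comparison,
)
from .metrics import GLOBAL_METRICS, NODAL_METRICS, GraphMetricsExtractor
from .simulate import SimulationConfig, generate_cohort, hub_deficit_config, read_cohort

logger = logging.getLogger(__name__)

# fixed per-stage offsets from the global seed, so stages are individually
# reproducible without sharing generator state
SEED_OFFSET_SIMULATION = 0
SEED_OFFSET_LOUVAIN = 104729


@dataclass
class RunConfig:
    """Serializable description of one pipeline run."""

    output_dir: str = "funconn_out"
    seed: int = 0
    # node table: path to a TSV, or None for the packaged synthetic atlas
    node_table: str | None = None
    min_size_voxels: int = 57
    excluded_classes: list[str] = field(default_factory=lambda: ["cerebellar"])
    # inputs: either a simulation block or time-series + covariate paths
    simulate: bool = True
    simulation: dict = field(
        default_factory=lambda: {"n_hubs": 3, "effect_delta": 0.3}
    )
    timeseries_dir: str | None = None
    covariates_path: str | None = None
    # analysis switches
    clip_z: float = 6.0
    weight_policy: str = "absolute"
    modularity_policy: str = "preserve"
    modularity_restarts: int = 20
    alpha: float = 0.05
    hub_top_fraction: float = 0.2
    include_iq_analysis: bool = True

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)


def _covariate_sets(include_iq: bool) -> dict[str, tuple[str, ...]]:
    sets = {
        "base": BASE_COVARIATES,
        "meanfc": BASE_COVARIATES + ("mean_fc",),
    }
    if include_iq:
        sets["iq"] = BASE_COVARIATES + ("iq",)
    return sets


def _build_cohort(cfg: RunConfig, node_ids: list[str]):
    if cfg.simulate:
        sim_kwargs = dict(cfg.simulation)
        n_hubs = sim_kwargs.pop("n_hubs", 0)
        delta = sim_kwargs.pop("effect_delta", 0.0)
        sim_kwargs.setdefault("n_nodes", len(node_ids))
        if n_hubs > 0 and delta != 0.0:
            sim_cfg = hub_deficit_config(
                n_hubs=n_hubs,
                effect_delta=delta,
                seed=cfg.seed + SEED_OFFSET_SIMULATION,
                **sim_kwargs,
            )
        else:
            sim_cfg = SimulationConfig(seed=cfg.seed + SEED_OFFSET_SIMULATION, **sim_kwargs)
        if sim_cfg.n_nodes != len(node_ids):
            raise ValueError(
                f"simulation n_nodes {sim_cfg.n_nodes} != node table yields {len(node_ids)}"
            )
        cohort, truth = generate_cohort(sim_cfg)
        for ts in cohort.series:  # relabel positional ids with atlas node ids
            ts.node_ids = list(node_ids)
        return cohort, truth
    if not cfg.timeseries_dir or not cfg.covariates_path:
        missing = "timeseries_dir" if not cfg.timeseries_dir else "covariates_path"
        raise FileNotFoundError(
            f"config has no simulation block and no {missing}; nothing to analyse"
        )
    return read_cohort(cfg.timeseries_dir, cfg.covariates_path), None


def _align_series(cohort, node_ids: list[str], merge_map: dict[str, str]):
    """Aggregate pre-merge region series onto the final node set when needed."""
    for idx, ts in enumerate(cohort.series):
        if ts.node_ids == node_ids:
            continue
        merged = aggregate_merged_series(ts, merge_map)
        keep = {n: k for k, n in enumerate(merged.node_ids)}
        missing = [n for n in node_ids if n not in keep]
        if missing:
            raise ValueError(f"time series missing final node(s): {missing[:5]}")
        order = [keep[n] for n in node_ids]
        merged.values = merged.values[:, order]
        merged.node_ids = list(node_ids)
        cohort.series[idx] = merged
    return cohort


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full analysis; returns the run report (also written as JSON)."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "config.yaml")
    report: dict = {"seed": cfg.seed, "stages": {}}

    # --- nodes -------------------------------------------------------------
    raw = atlas.load_node_table(cfg.node_table) if cfg.node_table else atlas.default_node_table()
    nodes, merge_map = atlas.build_nodes(
        raw, cfg.min_size_voxels, set(cfg.excluded_classes)
    )
    node_ids = list(nodes["region_id"])
    atlas.write_node_table(nodes, out / "nodes.tsv")
    (out / "merge_map.json").write_text(json.dumps(merge_map, indent=1, sort_keys=True))
    report["stages"]["nodes"] = {
        "rows_in": int(len(raw)),
        "nodes_out": int(len(nodes)),
    }
    logger.info("node table: %d rows -> %d nodes", len(raw), len(nodes))

    # --- cohort ------------------------------------------------------------
    cohort, truth = _build_cohort(cfg, node_ids)
    cohort = _align_series(cohort, node_ids, merge_map)
    n_sub = cohort.n_subjects
    if truth is not None:
        (out / "truth.json").write_text(truth.to_json())
    report["stages"]["cohort"] = {
        "n_subjects": n_sub,
        "n_controls": int((cohort.covariates["group"] == 0).sum()),
        "n_patients": int((cohort.covariates["group"] == 1).sum()),
        "t_samples": int(cohort.series[0].n_samples),
        "simulated": bool(cfg.simulate),
    }

    # --- connectivity ------------------------------------------------------
    conn = FisherZConnectivity(clip_z=cfg.clip_z)
    matrices = conn.fit_transform(cohort.series)
    covariates = cohort.covariates.copy()
    covariates["mean_fc"] = [
        float(matrices[s][np.triu_indices(len(node_ids), k=1)].mean())
        for s in range(n_sub)
    ]
    fc_dir = out / "fc_matrices"
    fc_dir.mkdir(exist_ok=True)
    for s, sid in enumerate(covariates["subject_id"]):
        pd.DataFrame(matrices[s], index=node_ids, columns=node_ids).to_csv(
            fc_dir / f"{sid}.tsv", sep="\t", float_format="%.8g"
        )
    covariates.to_csv(out / "covariates.csv", index=False, float_format="%.10g")
    report["stages"]["connectivity"] = {
        "n_matrices": n_sub,
        "n_nodes": len(node_ids),
        "clip_z": cfg.clip_z,
    }

    # --- graph metrics -----------------------------------------------------
    extractor = GraphMetricsExtractor(
        policy=cfg.weight_policy,
        modularity_policy=cfg.modularity_policy,
        n_restarts=cfg.modularity_restarts,
        seed=cfg.seed + SEED_OFFSET_LOUVAIN,
    )
    nodal, global_df = extractor.fit_transform(matrices)
    for name in NODAL_METRICS:
        df = pd.DataFrame(nodal[name], index=covariates["subject_id"], columns=node_ids)
        df.to_csv(out / f"nodal_{name}.tsv", sep="\t", float_format="%.8g")
    global_df.insert(0, "subject_id", covariates["subject_id"].to_numpy())
    global_df.to_csv(out / "global_metrics.tsv", sep="\t", index=False, float_format="%.8g")
    report["stages"]["metrics"] = {
        "nodal_metrics": list(NODAL_METRICS),
        "global_metrics": list(GLOBAL_METRICS),
    }

    # --- group inference ---------------------------------------------------
    comparisons: dict = {}
    for set_name, covs in _covariate_sets(cfg.include_iq_analysis).items():
        spec = DesignSpec(covariates=covs, alpha=cfg.alpha)
        edge_res = edgewise_comparison(matrices, covariates, spec, node_ids)
        edge_res.to_csv(out / f"edges_{set_name}.tsv", sep="\t", index=False, float_format="%.8g")
        sig = edge_res[edge_res["q"] <= cfg.alpha]
        decreased = sig[sig["t"] < 0]
        increased = sig[sig["t"] > 0]
        dec_edges = [tuple(u.split("|")) for u in decreased["unit_id"]]
        comparisons[set_name] = {
            "edges_tested": int(len(edge_res)),
            "edges_decreased": int(len(decreased)),
            "edges_increased": int(len(increased)),
            "decreased_categories": classify_edges(dec_edges, nodes),
        }
        nodal_summary = {}
        for metric in NODAL_METRICS:
            res = nodal_comparison(nodal[metric], covariates, spec, node_ids)
            res.to_csv(
                out / f"nodal_{metric}_{set_name}.tsv", sep="\t", index=False, float_format="%.8g"
            )
            nodal_summary[metric] = {
                "decreased": int(((res["q"] <= cfg.alpha) & (res["t"] < 0)).sum()),
                "increased": int(((res["q"] <= cfg.alpha) & (res["t"] > 0)).sum()),
            }
        comparisons[set_name]["nodal"] = nodal_summary
        glob_res = global_comparison(global_df[list(GLOBAL_METRICS)], covariates, spec)
        glob_res.to_csv(
            out / f"global_{set_name}.tsv", sep="\t", index=False, float_format="%.8g"
        )
        comparisons[set_name]["global"] = {
            row["unit_id"]: {"t": round(float(row["t"]), 6), "p": round(float(row["p"]), 6)}
            for _, row in glob_res.iterrows()
        }
    report["comparisons"] = comparisons

    # --- hub ranking (base covariate set, weighted degree) ------------------
    base_spec = DesignSpec(covariates=BASE_COVARIATES, alpha=cfg.alpha)
    degree_res = nodal_comparison(nodal["weighted_degree"], covariates, base_spec, node_ids)
    sig_nodes = set(
        degree_res.loc[(degree_res["q"] <= cfg.alpha) & (degree_res["t"] < 0), "unit_id"]
    )
    controls = covariates["group"].to_numpy() == 0
    control_mean_degree = nodal["weighted_degree"][controls].mean(axis=0)
    ranking, p_enrich = hub_ranking(
        control_mean_degree, sig_nodes, node_ids, cfg.hub_top_fraction
    )
    ranking.to_csv(out / "hub_ranking.tsv", sep="\t", index=False, float_format="%.8g")
    report["hub_analysis"] = {
        "significant_decreased_degree_nodes": sorted(sig_nodes),
        "hub_enrichment_p": p_enrich,
        "top_fraction": cfg.hub_top_fraction,
    }

    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report
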