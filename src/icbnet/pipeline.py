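"""End-to-end orchestration from a single validated configuration.

Stages: inputs (load or simulate) -> cluster networks -> topology ->
differential expression -> response model. Every stage writes its tables
into the result directory and a manifest records the configuration hash
and a checksum of every output file, so a re-run under the same
configuration and seed is byte-identical.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import degs, io, networks, response, simulate, topology

logger = logging.getLogger("icbnet")

DEFAULT_CONFIG: dict = {
    "synthetic": {
        "n_genes": 500,
        "mean_degree": 4,
        "n_cells": 1200,
        "n_clusters": 6,
        "n_samples": 12,
        "n_tfs": 40,
        "n_lr_pairs": 15,
        "bulk_samples": 56,
        "bulk_noise_sd": 0.5,
        "truth": {
            "modules_per_cluster": 4,
            "module_size": 5,
            "module_rho": 0.6,
            "n_deg_per_phase": 10,
            "deg_effect": 2.5,
            "n_predictive": 3,
            "n_decoys": 10,
        },
    },
    "inputs": {
        "expression": None,
        "metadata": None,
        "interactions": None,
        "tf_list": None,
        "lr_pairs": None,
        "bulk_expression": None,
        "bulk_response": None,
    },
    "thresholds": {
        "min_fraction": 0.01,
        "edge_alpha": 0.05,
        "fc_threshold": 2.0,
        "deg_alpha": 0.05,
    },
    "loop": {"n_iter": 500, "base_seed": 0, "max_sets": 17},
    "modes": {
        "prevalence_scope": "cluster",
        "feature_phase": "pooled",
        "stepwise_direction": "both",
        "stepwise_start": "empty",
    },
    "seed": 0,
}

_RANGES = {
    ("thresholds", "min_fraction"): (0.0, 1.0, False),
    ("thresholds", "edge_alpha"): (0.0, 1.0, True),
    ("thresholds", "deg_alpha"): (0.0, 1.0, True),
}
_ENUMS = {
    ("modes", "prevalence_scope"): {"cluster", "global"},
    ("modes", "feature_phase"): {"pre", "on", "pooled"},
    ("modes", "stepwise_direction"): {"both", "forward", "backward"},
    ("modes", "stepwise_start"): {"empty", "full"},
}


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    raw: dict

    def __getitem__(self, key):
        return self.raw[key]

    @property
    def is_synthetic(self) -> bool:
        return self.raw["inputs"]["expression"] is None

    def dump(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.raw, sort_keys=True))


def _merge(defaults: dict, user: dict, path: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, value in user.items():
        here = f"{path}.{key}" if path else key
        if key not in defaults:
            raise ConfigError(f"unknown configuration key: {here}")
        if isinstance(defaults[key], dict) and isinstance(value, dict):
            out[key] = _merge(defaults[key], value, here)
        else:
            out[key] = value
    return out


def validate_config(source: str | Path | dict) -> PipelineConfig:
    """Load, default-fill and range-check a YAML/JSON configuration.

    Unknown keys are an error. Exactly one of the synthetic block and the
    explicit input paths may be active: providing any input path disables
    simulation and then all seven paths are required.
    """
    if isinstance(source, dict):
        user = copy.deepcopy(source)
    else:
        text = Path(source).read_text()
        user = yaml.safe_load(text) or {}
    cfg = _merge(DEFAULT_CONFIG, user)

    for (section, key), (lo, hi, hi_open) in _RANGES.items():
        v = cfg[section][key]
        ok = lo <= v < hi if not hi_open else lo < v <= hi
        if not ok:
            raise ConfigError(f"{section}.{key}={v} out of range")
    if cfg["thresholds"]["fc_threshold"] < 1:
        raise ConfigError("thresholds.fc_threshold must be >= 1")
    if cfg["loop"]["n_iter"] < 1:
        raise ConfigError("loop.n_iter must be >= 1")
    for (section, key), allowed in _ENUMS.items():
        if cfg[section][key] not in allowed:
            raise ConfigError(
                f"{section}.{key}={cfg[section][key]!r} not in {sorted(allowed)}"
            )
    paths = cfg["inputs"]
    given = [k for k, v in paths.items() if v is not None]
    if given and len(given) != len(paths):
        missing = sorted(set(paths) - set(given))
        raise ConfigError(f"partial input paths; missing: {missing}")
    return PipelineConfig(raw=cfg)


# ---------------------------------------------------------------------------
# stages


def _stage_inputs(cfg: PipelineConfig, out: Path):
    if cfg.is_synthetic:
        syn = cfg["synthetic"]
        seed = cfg["seed"]
        catalog = simulate.generate_pathway_catalog(
            n_genes=syn["n_genes"], mean_degree=syn["mean_degree"], seed=seed
        )
        sets_ = simulate.generate_annotation_sets(
            catalog, n_tfs=syn["n_tfs"], n_lr_pairs=syn["n_lr_pairs"], seed=seed + 1
        )
        matrix, annotation, truth = simulate.generate_cells(
            catalog,
            simulate.TruthSpec(**syn["truth"]),
            n_cells=syn["n_cells"],
            n_clusters=syn["n_clusters"],
            n_samples=syn["n_samples"],
            seed=seed + 2,
            annotation_sets=sets_,
        )
        bulk = simulate.generate_bulk_cohort(
            truth,
            n_samples=syn["bulk_samples"],
            noise_sd=syn["bulk_noise_sd"],
            seed=seed + 3,
        )
        io.write_expression(matrix, out / "expression.tsv")
        io.write_cell_metadata(annotation, out / "cell_metadata.tsv")
        io.write_interactions(catalog, out / "interactions.sif")
        io.write_annotation_sets(sets_, out / "tf_list.txt", out / "lr_pairs.tsv")
        io.write_bulk_cohort(
            bulk, out / "bulk_expression.tsv", out / "bulk_response.tsv"
        )
        truth.to_json(out / "truth.json")
        return matrix, annotation, catalog, sets_, bulk
    paths = cfg["inputs"]
    matrix = io.read_expression(paths["expression"])
    annotation = io.read_cell_metadata(paths["metadata"], matrix=matrix)
    catalog = io.read_interactions(paths["interactions"])
    sets_ = io.read_annotation_sets(paths["tf_list"], paths["lr_pairs"])
    bulk = io.read_bulk_cohort(paths["bulk_expression"], paths["bulk_response"])
    return matrix, annotation, catalog, sets_, bulk


def _stage_networks(cfg, out, matrix, annotation, catalog, sets_):
    th, modes = cfg["thresholds"], cfg["modes"]
    nets = networks.build_all_cluster_networks(
        matrix,
        annotation,
        catalog,
        alpha=th["edge_alpha"],
        min_fraction=th["min_fraction"],
        prevalence_scope=modes["prevalence_scope"],
    )
    merged = networks.annotate_roles(networks.merge_networks(nets), sets_)
    for net in nets:
        single = networks.annotate_roles(networks.merge_networks([net]), sets_)
        io.write_network(
            single,
            out / f"network_cluster{net.cluster}.sif",
            out / f"network_cluster{net.cluster}.nodes.tsv",
        )
    io.write_network(
        merged, out / "regulation_network.sif", out / "regulation_network.nodes.tsv"
    )
    networks.network_summary(nets).to_csv(
        out / "network_summary.tsv", sep="\t", index=False
    )
    return nets, merged


def _stage_topology(cfg, out, nets, merged):
    summary = topology.topology_summary(nets)
    summary.to_csv(out / "topology_summary.tsv", sep="\t", index=False)
    n_clusters = len(nets)
    shared = topology.shared_subnetwork(merged, n_clusters)
    io.write_network(
        shared, out / "shared_subnetwork.sif", out / "shared_subnetwork.nodes.tsv"
    )
    overlap = topology.network_overlap(nets)
    report = {
        "n_shared_genes": len(overlap.shared_nodes),
        "n_shared_edges": len(overlap.shared_edges),
        "shared_genes": sorted(overlap.shared_nodes),
        "per_network_fraction": {
            str(k): v for k, v in sorted(overlap.per_network_fraction.items())
        },
    }
    (out / "overlap.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return summary, overlap


def _stage_degs(cfg, out, matrix, annotation, nets):
    th = cfg["thresholds"]
    frames = []
    for phase in ("pre", "on"):
        frames.append(
            degs.deg_table(
                degs.find_degs(
                    matrix, annotation, phase,
                    fc_threshold=th["fc_threshold"], alpha=th["deg_alpha"],
                )
            )
        )
        for net in nets:
            universe = sorted(net.nodes)
            if not universe:
                continue
            try:
                frames.append(
                    degs.deg_table(
                        degs.find_degs(
                            matrix, annotation, phase, scope=net.cluster,
                            fc_threshold=th["fc_threshold"],
                            alpha=th["deg_alpha"],
                            gene_universe=universe,
                        )
                    )
                )
            except ValueError:
                logger.warning("skipping empty stratum: cluster %d %s", net.cluster, phase)
    table = pd.concat(frames, ignore_index=True)
    table.to_csv(out / "deg_table.tsv", sep="\t", index=False)
    return table


def _stage_response(cfg, out, matrix, annotation, merged, bulk):
    loop, modes = cfg["loop"], cfg["modes"]
    table = response.build_feature_table(
        matrix, annotation, merged, phase=modes["feature_phase"]
    )
    runs, summary = response.run_selection_loop(
        table,
        n_iter=loop["n_iter"],
        base_seed=loop["base_seed"],
        direction=modes["stepwise_direction"],
        start=modes["stepwise_start"],
    )
    runs_df = pd.DataFrame(
        {
            "iteration": [r.iteration for r in runs],
            "seed": [r.seed for r in runs],
            "genes": [",".join(r.selected_genes) for r in runs],
            "train_auc": [r.train_auc for r in runs],
            "test_auc": [r.test_auc for r in runs],
            "ridged": [r.ridged for r in runs],
        }
    )
    runs_df.to_csv(out / "selection_runs.tsv", sep="\t", index=False)
    ranking = response.rank_gene_sets(runs, max_sets=loop["max_sets"])
    ranking.to_csv(out / "gene_set_ranking.tsv", sep="\t", index=False)

    rows = []
    for rank_i, genes_str in enumerate(ranking["genes"], 1):
        gene_set = genes_str.split(",")
        try:
            model = response.validate_external(gene_set, table, bulk)
        except (KeyError, ValueError) as exc:
            logger.warning("skipping gene set %s: %s", genes_str, exc)
            continue
        response.roc_points(model.validation_scores, bulk.response).to_csv(
            out / f"roc_set{rank_i}.tsv", sep="\t", index=False
        )
        rows.append(
            {
                "genes": genes_str,
                "discovery_auc": model.discovery_auc,
                "validation_auc": model.validation_auc,
            }
        )
    validation = pd.DataFrame(rows, columns=["genes", "discovery_auc", "validation_auc"])
    validation.to_csv(out / "validation_report.tsv", sep="\t", index=False)
    (out / "selection_summary.json").write_text(
        json.dumps(
            {k: v for k, v in summary.items() if k != "selection_frequency"},
            indent=1,
            sort_keys=True,
        )
    )
    freq = pd.DataFrame(
        sorted(summary["selection_frequency"].items()),
        columns=["gene", "selection_frequency"],
    )
    freq.to_csv(out / "selection_frequency.tsv", sep="\t", index=False)
    return runs, ranking, validation


def run_pipeline(config: PipelineConfig | dict | str | Path, out_dir: str | Path) -> Path:
    """Execute every stage and write a checksummed manifest. Returns out_dir."""
    cfg = config if isinstance(config, PipelineConfig) else validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.dump(out / "config.yaml")

    stage = "inputs"
    try:
        matrix, annotation, catalog, sets_, bulk = _stage_inputs(cfg, out)
        stage = "networks"
        nets, merged = _stage_networks(cfg, out, matrix, annotation, catalog, sets_)
        stage = "topology"
        _stage_topology(cfg, out, nets, merged)
        stage = "differential_expression"
        _stage_degs(cfg, out, matrix, annotation, nets)
        stage = "response_model"
        _stage_response(cfg, out, matrix, annotation, merged, bulk)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    files = sorted(p for p in out.iterdir() if p.is_file() and p.name != "manifest.json")
    manifest = {
        "config_sha256": hashlib.sha256(
            yaml.safe_dump(cfg.raw, sort_keys=True).encode()
        ).hexdigest(),
        "seed": cfg["seed"],
        "outputs": {
            p.name: hashlib.sha256(p.read_bytes()).hexdigest() for p in files
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out
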