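"""Synthetic inputs with planted, fully known structure.

The generator emulates the five inputs of the pipeline — a clustered
single-cell expression matrix, cell metadata, a typed interaction
catalogue, TF/ligand/receptor role lists and a bulk validation cohort —
with three kinds of planted signal:

* **co-expression modules** per cluster: small groups of catalogue-adjacent
  genes share a Gaussian latent factor added to their log-rate before
  Poisson count sampling, so module pairs are rank-correlated in exactly
  one cluster's cells;
* **differential genes**: a response effect (multiplicative rate shift for
  responder cells of one phase); a subset of ligand/receptor genes carries
  the effect in both phases and also drives the bulk cohort ("predictive"
  genes);
* **decoy genes** detected in exactly 1% of cells, constructed (not
  sampled) so the strict >1% prevalence filter must remove them.

Counts are Poisson with log-normal rate heterogeneity (an overdispersed,
negative-binomial-like marginal); stored expression is log1p(counts).
All generators are deterministic in their seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .io import (
    AnnotationSets,
    BulkCohort,
    ExpressionMatrix,
    PathwayInteractionSet,
)

#: the interaction-type vocabulary used by default (13 types, matching the
#: extended-SIF vocabulary of pathway databases)
DEFAULT_TYPE_VOCAB = (
    "controls-expression-of",
    "controls-state-change-of",
    "controls-phosphorylation-of",
    "controls-transport-of",
    "controls-production-of",
    "controls-transport-of-chemical",
    "catalysis-precedes",
    "in-complex-with",
    "interacts-with",
    "chemical-affects",
    "consumption-controlled-by",
    "reacts-with",
    "used-to-produce",
)

#: per-gene-cell log-rate noise; sets the overdispersion of the counts
LOGRATE_SD = 0.3


@dataclass
class TruthSpec:
    """Declared planted structure for :func:`generate_cells`."""

    modules_per_cluster: int = 4
    module_size: int = 5
    module_rho: float = 0.6  # latent log-rate correlation within a module
    n_deg_per_phase: int = 10
    deg_effect: float = 2.5  # linear fold change, R over NR
    n_predictive: int = 3  # ligand/receptor genes carrying the signal
    n_decoys: int = 10


@dataclass
class SyntheticTruth:
    """Ground truth of one synthetic draw."""

    planted_edges_per_cluster: dict[int, set[tuple[str, str]]]
    planted_deg: dict[str, dict[str, float]]  # phase -> gene -> signed linear fold
    predictive_lr_genes: list[str]
    decoy_genes: list[str]
    base_log_mean: dict[str, float]
    generator_params: dict

    @property
    def module_genes(self) -> set[str]:
        out: set[str] = set()
        for pairs in self.planted_edges_per_cluster.values():
            for a, b in pairs:
                out.add(a)
                out.add(b)
        return out

    @property
    def deg_genes(self) -> set[str]:
        out: set[str] = set()
        for effects in self.planted_deg.values():
            out.update(effects)
        return out

    @property
    def special_genes(self) -> set[str]:
        """Every gene carrying any planted signal (for building null sets)."""
        return (
            self.module_genes
            | self.deg_genes
            | set(self.predictive_lr_genes)
            | set(self.decoy_genes)
        )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "planted_edges_per_cluster": {
                str(k): sorted(map(list, v))
                for k, v in self.planted_edges_per_cluster.items()
            },
            "planted_deg": self.planted_deg,
            "predictive_lr_genes": self.predictive_lr_genes,
            "decoy_genes": self.decoy_genes,
            "base_log_mean": self.base_log_mean,
            "generator_params": self.generator_params,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


# ---------------------------------------------------------------------------
# interaction catalogue


def generate_pathway_catalog(
    n_genes: int = 500,
    mean_degree: int = 4,
    type_vocab: tuple[str, ...] = DEFAULT_TYPE_VOCAB,
    seed: int = 0,
) -> PathwayInteractionSet:
    """Preferential-attachment interaction catalogue with typed edges.

    A Barabási–Albert graph gives the catalogue the heavy-tailed degree
    distribution real pathway databases show, so subnetworks drawn from it
    can be scale-free. Each edge gets a uniform type and random direction.
    """
    if n_genes < 50:
        raise ValueError("n_genes must be >= 50")
    if mean_degree < 2:
        raise ValueError("mean_degree must be >= 2")
    m = max(1, mean_degree // 2)
    if m >= n_genes:
        raise ValueError("mean_degree too large for n_genes")
    rng = np.random.default_rng(seed)
    graph = nx.barabasi_albert_graph(n_genes, m, seed=int(rng.integers(2**31)))
    width = len(str(n_genes))
    names = [f"G{i + 1:0{width}d}" for i in range(n_genes)]
    records = []
    for u, v in sorted(graph.edges()):
        itype = type_vocab[int(rng.integers(len(type_vocab)))]
        if rng.random() < 0.5:
            u, v = v, u
        records.append((names[u], itype, names[v]))
    return PathwayInteractionSet(records)


def generate_annotation_sets(
    catalog: PathwayInteractionSet,
    n_tfs: int = 40,
    n_lr_pairs: int = 15,
    seed: int = 0,
) -> AnnotationSets:
    """Random TF and ligand-receptor role assignments over catalogue genes."""
    rng = np.random.default_rng(seed)
    genes = sorted(catalog.genes)
    if n_tfs + 2 * n_lr_pairs > len(genes):
        raise ValueError("not enough genes for requested roles")
    picks = rng.choice(len(genes), size=n_tfs + 2 * n_lr_pairs, replace=False)
    tfs = {genes[i] for i in picks[:n_tfs]}
    rest = [genes[i] for i in picks[n_tfs:]]
    pairs = {(rest[2 * i], rest[2 * i + 1]) for i in range(n_lr_pairs)}
    return AnnotationSets(tfs=tfs, lr_pairs=pairs)


# ---------------------------------------------------------------------------
# cells


def generate_cells(
    catalog: PathwayInteractionSet,
    truth_spec: TruthSpec,
    n_cells: int = 1200,
    n_clusters: int = 6,
    n_samples: int = 12,
    seed: int = 0,
    annotation_sets: AnnotationSets | None = None,
) -> tuple[ExpressionMatrix, pd.DataFrame, SyntheticTruth]:
    """Clustered cells with planted modules, response effects and decoys.

    Samples split half responder / half non-responder and, within each
    response arm, half pre- / half on-treatment; every cell belongs to one
    sample. When *annotation_sets* is given, the predictive genes are drawn
    from its ligands and receptors (the invariant downstream feature
    selection relies on).
    """
    if n_samples % 2:
        raise ValueError("n_samples must be even (half R, half NR)")
    spec = truth_spec
    rng = np.random.default_rng(seed)
    genes = sorted(catalog.genes)
    gene_idx = {g: i for i, g in enumerate(genes)}
    n_genes = len(genes)

    # undirected adjacency of the catalogue, for module picking
    adj: dict[str, set[str]] = {g: set() for g in genes}
    pair_set: set[tuple[str, str]] = set()
    for s, _, t in catalog:
        adj[s].add(t)
        adj[t].add(s)
        pair_set.add((min(s, t), max(s, t)))

    # --- samples and cells -------------------------------------------------
    sample_ids = [f"S{i + 1:02d}" for i in range(n_samples)]
    half = n_samples // 2
    responses = ["R"] * half + ["NR"] * (n_samples - half)
    phases = [("pre" if i % 2 == 0 else "on") for i in range(n_samples)]
    cell_ids = [f"C{i + 1:05d}" for i in range(n_cells)]
    cell_sample = rng.integers(n_samples, size=n_cells)
    cell_cluster = rng.integers(1, n_clusters + 1, size=n_cells)
    annotation = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "cluster": cell_cluster,
            "sample_id": [sample_ids[i] for i in cell_sample],
            "phase": [phases[i] for i in cell_sample],
            "response": [responses[i] for i in cell_sample],
        }
    )

    # --- decoys ------------------------------------------------------------
    perm = rng.permutation(n_genes)
    decoys = [genes[i] for i in perm[: spec.n_decoys]]
    usable = [genes[i] for i in perm[spec.n_decoys :]]
    decoy_set = set(decoys)

    # --- baseline expression level per gene --------------------------------
    base_log_mean = {g: float(rng.normal(0.7, 0.8)) for g in genes}

    # --- planted modules ---------------------------------------------------
    planted_edges: dict[int, set[tuple[str, str]]] = {}
    module_assignments: dict[int, list[list[str]]] = {}
    hub_candidates = [
        g for g in usable if len(adj[g] - decoy_set) >= spec.module_size - 1
    ]
    rng.shuffle(hub_candidates)
    if len(hub_candidates) < n_clusters * spec.modules_per_cluster:
        raise ValueError("catalogue too sparse for the requested modules")
    hub_iter = iter(hub_candidates)
    for k in range(1, n_clusters + 1):
        mods: list[list[str]] = []
        used: set[str] = set()
        pairs: set[tuple[str, str]] = set()
        while len(mods) < spec.modules_per_cluster:
            hub = next(hub_iter, None)
            if hub is None:
                raise ValueError("catalogue too sparse for the requested modules")
            neigh = sorted((adj[hub] - decoy_set) - used - {hub})
            if hub in used or len(neigh) < spec.module_size - 1:
                continue
            members = [hub] + [
                neigh[i]
                for i in rng.choice(len(neigh), spec.module_size - 1, replace=False)
            ]
            mods.append(members)
            used.update(members)
            for a in members:
                for b in members:
                    if a < b and (a, b) in pair_set:
                        pairs.add((a, b))
        module_assignments[k] = mods
        planted_edges[k] = pairs

    for k, pairs in planted_edges.items():
        for a, b in pairs:
            if (min(a, b), max(a, b)) not in pair_set:
                raise ValueError(f"planted pair ({a},{b}) not in catalogue")

    # module genes need headroom above the detection floor
    for mods in module_assignments.values():
        for members in mods:
            for g in members:
                base_log_mean[g] = max(base_log_mean[g], float(np.log(5.0)))

    # --- planted response effects ------------------------------------------
    if annotation_sets is not None:
        lr_pool = sorted(
            (annotation_sets.ligands | annotation_sets.receptors)
            & set(usable)
        )
    else:
        lr_pool = list(usable)
    lr_pool = [g for g in lr_pool if adj[g] - decoy_set]
    if len(lr_pool) < spec.n_predictive:
        raise ValueError("not enough ligand/receptor genes for predictive set")
    predictive = [
        lr_pool[i]
        for i in rng.choice(len(lr_pool), spec.n_predictive, replace=False)
    ]
    # anchor each predictive gene with a two-gene co-expression module on a
    # catalogue neighbour, guaranteeing it a network edge in some cluster
    for i, g in enumerate(predictive):
        neigh = sorted(adj[g] - decoy_set)
        partner = neigh[int(rng.integers(len(neigh)))]
        k = (i % n_clusters) + 1
        module_assignments[k].append([g, partner])
        planted_edges[k].add((min(g, partner), max(g, partner)))
        base_log_mean[partner] = max(base_log_mean[partner], float(np.log(5.0)))
    deg_pool = [g for g in usable if g not in set(predictive)]
    planted_deg: dict[str, dict[str, float]] = {"pre": {}, "on": {}}
    for phase in ("pre", "on"):
        n_extra = max(spec.n_deg_per_phase - spec.n_predictive, 0)
        extra_idx = rng.choice(len(deg_pool), n_extra, replace=False)
        for g in predictive:
            planted_deg[phase][g] = spec.deg_effect  # up in responders
        for i in extra_idx:
            g = deg_pool[i]
            fold = spec.deg_effect if rng.random() < 0.5 else 1.0 / spec.deg_effect
            planted_deg[phase][g] = fold
    # differential genes sit well above the pseudo-count floor so the
    # twofold gate is decidable on the linear scale
    for effects in planted_deg.values():
        for g in effects:
            base_log_mean[g] = max(base_log_mean[g], float(np.log(10.0)))

    # --- count sampling -----------------------------------------------------
    log_rate = np.tile(
        np.array([base_log_mean[g] for g in genes])[:, None], (1, n_cells)
    )
    # module latent factors (per cluster, per module, per cell)
    loading = LOGRATE_SD * np.sqrt(spec.module_rho / (1.0 - spec.module_rho))
    for k, mods in module_assignments.items():
        in_k = np.flatnonzero(cell_cluster == k)
        for members in mods:
            f = rng.normal(size=in_k.size)
            for g in members:
                log_rate[gene_idx[g], in_k] += loading * f
    # response effects
    is_r = annotation["response"].to_numpy() == "R"
    phase_arr = annotation["phase"].to_numpy()
    for phase, effects in planted_deg.items():
        target = np.flatnonzero(is_r & (phase_arr == phase))
        for g, fold in effects.items():
            log_rate[gene_idx[g], target] += float(np.log(fold))
    # per-entry log-normal heterogeneity, then Poisson counts
    log_rate += rng.normal(scale=LOGRATE_SD, size=log_rate.shape)
    counts = rng.poisson(np.exp(log_rate)).astype(float)

    # decoys: detected in exactly floor(1% of cells) cells (constructed)
    n_detect = int(np.floor(0.01 * n_cells))
    for g in decoys:
        row = gene_idx[g]
        counts[row, :] = 0.0
        if n_detect:
            cols = rng.choice(n_cells, size=n_detect, replace=False)
            counts[row, cols] = 1.0

    matrix = ExpressionMatrix(genes, cell_ids, np.log1p(counts))
    truth = SyntheticTruth(
        planted_edges_per_cluster=planted_edges,
        planted_deg=planted_deg,
        predictive_lr_genes=predictive,
        decoy_genes=decoys,
        base_log_mean=base_log_mean,
        generator_params={
            "n_cells": n_cells,
            "n_clusters": n_clusters,
            "n_samples": n_samples,
            "seed": seed,
            "lograte_sd": LOGRATE_SD,
            **asdict(spec),
        },
    )
    return matrix, annotation, truth


# ---------------------------------------------------------------------------
# bulk cohort


def generate_bulk_cohort(
    truth: SyntheticTruth,
    n_samples: int = 56,
    noise_sd: float = 0.5,
    seed: int = 0,
    n_responders: int | None = None,
    effect_scale: float = 1.0,
) -> BulkCohort:
    """Independent bulk cohort sharing the planted predictive signal.

    Sample value = the gene's population log-mean, plus (predictive genes
    only, responders only) the truth's signed log-fold effect scaled by
    *effect_scale*, plus Gaussian noise.
    """
    if n_samples < 6:
        raise ValueError("n_samples must be >= 6")
    rng = np.random.default_rng(seed)
    if n_responders is None:
        n_responders = max(2, round(n_samples * 22 / 56))
    if not 2 <= n_responders <= n_samples - 2:
        raise ValueError("need >= 2 samples in each class")
    genes = sorted(truth.base_log_mean)
    gene_idx = {g: i for i, g in enumerate(genes)}
    response = ["R"] * n_responders + ["NR"] * (n_samples - n_responders)
    base = np.array([truth.base_log_mean[g] for g in genes])
    values = np.tile(base, (n_samples, 1))
    pooled_effect: dict[str, float] = {}
    for g in truth.predictive_lr_genes:
        folds = [
            truth.planted_deg[ph][g]
            for ph in truth.planted_deg
            if g in truth.planted_deg[ph]
        ]
        pooled_effect[g] = float(np.mean(np.log(folds))) if folds else 0.0
    r_rows = np.arange(n_responders)
    for g, eff in pooled_effect.items():
        values[r_rows, gene_idx[g]] += effect_scale * eff
    values += rng.normal(scale=noise_sd, size=values.shape)
    return BulkCohort(
        sample_ids=[f"B{i + 1:02d}" for i in range(n_samples)],
        gene_ids=genes,
        values=values,
        response=response,
    )
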