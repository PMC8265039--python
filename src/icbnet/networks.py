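"""Cluster-specific co-expression networks constrained by a pathway catalogue.

Two genes are linked in the network of an immune cell cluster when
(a) each is detected in strictly more than ``min_fraction`` of the cells,
(b) the pathway catalogue records a typed interaction between them, and
(c) the Spearman correlation test of their expression over those cells
has p < alpha.

Cluster networks are merged into a single regulation network carrying
per-edge and per-node cluster membership, then annotated with
transcription-factor / ligand / receptor roles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import AnnotationSets, ExpressionMatrix, PathwayInteractionSet

logger = logging.getLogger("icbnet")

Edge = tuple[str, str, str]  # (source, interaction_type, target)

#: interaction types treated as undirected (stored in lexicographic
#: endpoint order so the same physical edge is never duplicated)
UNDIRECTED_TYPES = frozenset({"in-complex-with", "interacts-with"})


def canonical_edge(source: str, itype: str, target: str) -> Edge:
    if itype in UNDIRECTED_TYPES and source > target:
        source, target = target, source
    return (source, itype, target)


@dataclass
class ClusterNetwork:
    """One immune cell cluster's network: catalogue edges with (rho, p)."""

    cluster: int
    edges: dict[Edge, tuple[float, float]]
    # construction diagnostics (None when the network was not built here)
    n_candidates: int | None = None
    n_failed_prevalence: int | None = None
    n_failed_correlation: int | None = None

    @property
    def nodes(self) -> set[str]:
        out: set[str] = set()
        for s, _, t in self.edges:
            out.add(s)
            out.add(t)
        return out

    @property
    def edge_keys(self) -> set[Edge]:
        return set(self.edges)


@dataclass
class RegulationNetwork:
    """Union of cluster networks with membership sets and role flags."""

    edge_clusters: dict[Edge, set[int]]
    node_clusters: dict[str, set[int]]
    # gene -> (is_tf, is_ligand, is_receptor)
    roles: dict[str, tuple[bool, bool, bool]] = field(default_factory=dict)

    @property
    def nodes(self) -> set[str]:
        return set(self.node_clusters)

    @property
    def n_edges(self) -> int:
        return len(self.edge_clusters)

    def role_counts(self) -> dict[str, int]:
        flags = [self.roles.get(g, (False, False, False)) for g in self.node_clusters]
        return {
            "tfs": sum(f[0] for f in flags),
            "ligands": sum(f[1] for f in flags),
            "receptors": sum(f[2] for f in flags),
        }

    def genes_with_role(self, role: str) -> set[str]:
        idx = {"tf": 0, "ligand": 1, "receptor": 2}[role]
        return {
            g
            for g in self.node_clusters
            if self.roles.get(g, (False, False, False))[idx]
        }


# ---------------------------------------------------------------------------
# condition (a): prevalence


def expressed_genes(
    matrix: ExpressionMatrix,
    cells: Sequence[str],
    min_fraction: float = 0.01,
) -> set[str]:
    """Genes detected (value > 0) in strictly more than *min_fraction* of *cells*."""
    if len(cells) == 0:
        raise ValueError("empty cell list")
    if not 0 <= min_fraction < 1:
        raise ValueError(f"min_fraction {min_fraction} outside [0, 1)")
    sub = matrix.cell_columns(cells)
    frac = (sub > 0).sum(axis=1) / len(cells)
    return {g for g, f in zip(matrix.gene_ids, frac) if f > min_fraction}


# ---------------------------------------------------------------------------
# condition (c): Spearman correlation test


def spearman_edge_test(
    matrix: ExpressionMatrix,
    cells: Sequence[str],
    gene_a: str,
    gene_b: str,
) -> tuple[float, float]:
    """Spearman rho and two-sided p for one gene pair over the given cells.

    Ties get average ranks; p comes from the t approximation. If either
    vector is constant the correlation is undefined and (nan, 1.0) is
    returned by contract.
    """
    if len(cells) < 4:
        raise ValueError("need at least 4 cells for a correlation test")
    x = matrix.gene_row(gene_a)[[matrix._cell_index[c] for c in cells]]
    y = matrix.gene_row(gene_b)[[matrix._cell_index[c] for c in cells]]
    if np.all(x == x[0]) or np.all(y == y[0]):
        return (float("nan"), 1.0)
    res = stats.spearmanr(x, y)
    return (float(res.statistic), float(res.pvalue))


def _spearman_pairs(
    X: np.ndarray, pairs_a: np.ndarray, pairs_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Spearman (rho, p) for many row pairs of ``X`` (genes x cells).

    Ranks each row once (average ranks), then computes the Pearson
    correlation of rank vectors per requested pair and the two-sided p from
    the t approximation — the same statistic scipy's ``spearmanr`` reports.
    Constant rows yield (nan, 1.0).
    """
    n = X.shape[1]
    R = stats.rankdata(X, axis=1)
    R = R - R.mean(axis=1, keepdims=True)
    norm = np.sqrt((R**2).sum(axis=1))
    constant = norm == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        num = (R[pairs_a] * R[pairs_b]).sum(axis=1)
        rho = num / (norm[pairs_a] * norm[pairs_b])
    rho = np.clip(rho, -1.0, 1.0)
    bad = constant[pairs_a] | constant[pairs_b]
    with np.errstate(invalid="ignore", divide="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(rho) == 1.0, 0.0, p)
    rho = np.where(bad, np.nan, rho)
    p = np.where(bad, 1.0, p)
    return rho, p


# ---------------------------------------------------------------------------
# per-cluster construction


def candidate_edges(
    interactions: PathwayInteractionSet, expressed: set[str]
) -> list[Edge]:
    """Catalogue triples whose both endpoints pass the prevalence filter,
    canonicalized (undirected types in endpoint order) and deduplicated."""
    seen: set[Edge] = set()
    out: list[Edge] = []
    for s, t, o in interactions:
        if s in expressed and o in expressed:
            e = canonical_edge(s, t, o)
            if e not in seen:
                seen.add(e)
                out.append(e)
    return out


def build_cluster_network(
    matrix: ExpressionMatrix,
    annotation: pd.DataFrame,
    cluster: int,
    interactions: PathwayInteractionSet,
    alpha: float = 0.05,
    min_fraction: float = 0.01,
    prevalence_scope: str = "cluster",
) -> ClusterNetwork:
    """Build one cluster-specific network under the three edge conditions.

    *prevalence_scope* selects the denominator of condition (a): the
    cluster's own cells (default) or every cell in the matrix ("global").
    The correlation of condition (c) is always computed on the cluster's
    cells. Isolated nodes cannot occur: a node exists only via a retained
    edge.
    """
    cells = annotation.loc[annotation["cluster"] == cluster, "cell_id"].tolist()
    if cluster not in set(annotation["cluster"]):
        raise ValueError(f"cluster {cluster} absent from annotation")
    if len(cells) < 4:
        raise ValueError(f"cluster {cluster} has {len(cells)} cells; need >= 4")
    prev_cells = matrix.cell_ids if prevalence_scope == "global" else cells
    expressed = expressed_genes(matrix, prev_cells, min_fraction)
    cand = candidate_edges(interactions, expressed)
    n_catalogue = len({canonical_edge(*r) for r in interactions})
    n_failed_prev = n_catalogue - len(cand)
    if not cand:
        return ClusterNetwork(
            cluster=cluster, edges={}, n_candidates=0,
            n_failed_prevalence=n_failed_prev, n_failed_correlation=0,
        )

    gene_idx = matrix._gene_index
    sub = matrix.cell_columns(cells)
    pairs_a = np.array([gene_idx[e[0]] for e in cand])
    pairs_b = np.array([gene_idx[e[2]] for e in cand])
    rho, p = _spearman_pairs(sub, pairs_a, pairs_b)
    edges = {
        e: (float(r), float(pv))
        for e, r, pv in zip(cand, rho, p)
        if pv < alpha
    }
    logger.info(
        "cluster %d: %d candidates, %d retained (alpha=%g)",
        cluster, len(cand), len(edges), alpha,
    )
    return ClusterNetwork(
        cluster=cluster,
        edges=edges,
        n_candidates=len(cand),
        n_failed_prevalence=n_failed_prev,
        n_failed_correlation=len(cand) - len(edges),
    )


def build_all_cluster_networks(
    matrix: ExpressionMatrix,
    annotation: pd.DataFrame,
    interactions: PathwayInteractionSet,
    alpha: float = 0.05,
    min_fraction: float = 0.01,
    prevalence_scope: str = "cluster",
) -> list[ClusterNetwork]:
    clusters = sorted(annotation["cluster"].unique())
    return [
        build_cluster_network(
            matrix, annotation, int(k), interactions,
            alpha=alpha, min_fraction=min_fraction,
            prevalence_scope=prevalence_scope,
        )
        for k in clusters
    ]


def network_summary(networks: Iterable[ClusterNetwork]) -> pd.DataFrame:
    rows = [
        {
            "cluster": n.cluster,
            "n_nodes": len(n.nodes),
            "n_edges": len(n.edges),
            "n_candidates": n.n_candidates,
            "n_failed_prevalence": n.n_failed_prevalence,
            "n_failed_correlation": n.n_failed_correlation,
        }
        for n in networks
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# merge + roles


def merge_networks(cluster_networks: Sequence[ClusterNetwork]) -> RegulationNetwork:
    """Union of cluster networks keyed by (source, type, target).

    Per-edge and per-node membership sets record the contributing clusters.
    """
    if not cluster_networks:
        raise ValueError("need at least one cluster network")
    edge_clusters: dict[Edge, set[int]] = {}
    node_clusters: dict[str, set[int]] = {}
    for net in cluster_networks:
        for e in net.edges:
            edge_clusters.setdefault(e, set()).add(net.cluster)
            for g in (e[0], e[2]):
                node_clusters.setdefault(g, set()).add(net.cluster)
    return RegulationNetwork(edge_clusters=edge_clusters, node_clusters=node_clusters)


def annotate_roles(
    network: RegulationNetwork, annotation_sets: AnnotationSets
) -> RegulationNetwork:
    """Set TF/ligand/receptor flags on the network's nodes (in place)."""
    for gene in network.node_clusters:
        network.roles[gene] = (
            gene in annotation_sets.tfs,
            gene in annotation_sets.ligands,
            gene in annotation_sets.receptors,
        )
    counts = network.role_counts()
    logger.info(
        "annotated roles: %d TFs, %d ligands, %d receptors",
        counts["tfs"], counts["ligands"], counts["receptors"],
    )
    return network
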