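"""Degree-distribution power-law fits and cross-network overlap statistics.

Scale-free topology is checked the classical way: the fraction Y of nodes
with degree X should follow Y = a * X^(-b), i.e. log10 Y is linear in
log10 X, and the fit is ordinary least squares on the log-log points.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .networks import ClusterNetwork, Edge, RegulationNetwork


@dataclass
class DegreeFit:
    """Power-law fit Y = a * X^(-b) of a degree distribution."""

    a: float
    b: float
    r_squared: float
    points: list[tuple[int, float]]


@dataclass
class OverlapSummary:
    shared_nodes: set[str]
    shared_edges: set[Edge]
    per_network_fraction: dict[int, float]


def _edge_keys(network) -> set[Edge]:
    if isinstance(network, ClusterNetwork):
        return set(network.edges)
    if isinstance(network, RegulationNetwork):
        return set(network.edge_clusters)
    return set(network)


def _node_keys(network) -> set[str]:
    edges = _edge_keys(network)
    out: set[str] = set()
    for s, _, t in edges:
        out.add(s)
        out.add(t)
    return out


def degree_distribution(network) -> list[tuple[int, float]]:
    """(degree, fraction of nodes) pairs, direction ignored.

    Multi-edges between the same gene pair with different interaction types
    count as distinct incidences, since edges are typed objects throughout.
    """
    edges = _edge_keys(network)
    if not edges:
        raise ValueError("empty network")
    deg: Counter[str] = Counter()
    for s, _, t in edges:
        deg[s] += 1
        deg[t] += 1
    n = len(deg)
    counts = Counter(deg.values())
    return sorted((d, c / n) for d, c in counts.items())


def fit_power_law(distribution: Sequence[tuple[int, float]]) -> DegreeFit:
    """OLS fit of log10(fraction) on log10(degree).

    Returns a = 10^intercept, b = -slope and the regression r^2. Requires
    at least 3 distinct degrees with positive fraction.
    """
    pts = [(x, y) for x, y in distribution if x >= 1 and y > 0]
    if len(pts) < 3:
        raise ValueError(f"need >= 3 distinct degrees to fit, got {len(pts)}")
    lx = np.log10([x for x, _ in pts])
    ly = np.log10([y for _, y in pts])
    slope, intercept = np.polyfit(lx, ly, 1)
    resid = ly - (slope * lx + intercept)
    ss_res = float((resid**2).sum())
    ss_tot = float(((ly - ly.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return DegreeFit(
        a=float(10**intercept),
        b=float(-slope),
        r_squared=float(r2),
        points=list(pts),
    )


def network_overlap(networks: Sequence) -> OverlapSummary:
    """Exact node/edge intersections across networks plus per-network
    shared-edge fractions."""
    if len(networks) < 2:
        raise ValueError("need >= 2 networks")
    edge_sets = [_edge_keys(n) for n in networks]
    node_sets = [_node_keys(n) for n in networks]
    shared_edges = set.intersection(*edge_sets)
    shared_nodes = set.intersection(*node_sets)
    fractions: dict[int, float] = {}
    for i, (net, es) in enumerate(zip(networks, edge_sets)):
        key = net.cluster if isinstance(net, ClusterNetwork) else i
        fractions[key] = len(shared_edges) / len(es) if es else 0.0
    return OverlapSummary(
        shared_nodes=shared_nodes,
        shared_edges=shared_edges,
        per_network_fraction=fractions,
    )


def shared_subnetwork(
    regulation_network: RegulationNetwork, n_networks: int
) -> RegulationNetwork:
    """Edges present in exactly *n_networks* cluster networks, as a network."""
    edge_clusters = {
        e: set(ms)
        for e, ms in regulation_network.edge_clusters.items()
        if len(ms) == n_networks
    }
    node_clusters: dict[str, set[int]] = {}
    for e, ms in edge_clusters.items():
        for g in (e[0], e[2]):
            node_clusters.setdefault(g, set()).update(ms)
    roles = {
        g: regulation_network.roles[g]
        for g in node_clusters
        if g in regulation_network.roles
    }
    return RegulationNetwork(
        edge_clusters=edge_clusters, node_clusters=node_clusters, roles=roles
    )


def pairwise_jaccard(networks: Sequence) -> np.ndarray:
    """Symmetric matrix of edge-set Jaccard indices between networks."""
    if len(networks) < 2:
        raise ValueError("need >= 2 networks")
    sets_ = [_edge_keys(n) for n in networks]
    k = len(sets_)
    out = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            union = len(sets_[i] | sets_[j])
            inter = len(sets_[i] & sets_[j])
            out[i, j] = out[j, i] = inter / union if union else 0.0
    return out


def topology_summary(networks: Sequence[ClusterNetwork]) -> pd.DataFrame:
    """Per-network table: size plus power-law fit parameters."""
    rows = []
    for net in networks:
        row = {
            "cluster": net.cluster,
            "n_nodes": len(net.nodes),
            "n_edges": len(net.edges),
        }
        try:
            fit = fit_power_law(degree_distribution(net))
            row.update(a=fit.a, b=fit.b, r_squared=fit.r_squared)
        except ValueError:
            row.update(a=np.nan, b=np.nan, r_squared=np.nan)
        rows.append(row)
    return pd.DataFrame(rows)
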