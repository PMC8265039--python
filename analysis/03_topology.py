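#!/usr/bin/env python
"""Check scale-free topology (log-log OLS power-law fits of the degree
distributions) and cross-network overlap: genes/edges shared by every
cluster network and the shared-core subnetwork."""

import json
from pathlib import Path

from icbnet import io, networks, topology

NET_DIR = Path("results/networks")
OUT = Path("results/topology")


def load_cluster_networks():
    nets = []
    for sif in sorted(NET_DIR.glob("network_cluster*.sif")):
        cluster = int(sif.stem.replace("network_cluster", ""))
        reg = io.read_network(sif, sif.with_suffix("").with_suffix(".nodes.tsv"))
        nets.append(
            networks.ClusterNetwork(
                cluster, {e: (float("nan"), 0.0) for e in reg.edge_clusters}
            )
        )
    return nets


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    nets = load_cluster_networks()
    merged = io.read_network(
        NET_DIR / "regulation_network.sif", NET_DIR / "regulation_network.nodes.tsv"
    )

    summary = topology.topology_summary(nets)
    summary.to_csv(OUT / "topology_summary.tsv", sep="\t", index=False)
    overlap = topology.network_overlap(nets)
    shared = topology.shared_subnetwork(merged, len(nets))
    io.write_network(
        shared, OUT / "shared_subnetwork.sif", OUT / "shared_subnetwork.nodes.tsv"
    )
    (OUT / "overlap.json").write_text(
        json.dumps(
            {
                "n_shared_genes": len(overlap.shared_nodes),
                "n_shared_edges": len(overlap.shared_edges),
                "shared_genes": sorted(overlap.shared_nodes),
            },
            indent=1,
        )
    )

    print(summary.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
    print(f"power-law exponent b in "
          f"[{summary['b'].min():.2f}, {summary['b'].max():.2f}], "
          f"r^2 in [{summary['r_squared'].min():.2f}, {summary['r_squared'].max():.2f}]")
    print(f"shared by all {len(nets)} networks: {len(overlap.shared_nodes)} genes, "
          f"{len(overlap.shared_edges)} edges")
    print(f"tables written to {OUT}/")


if __name__ == "__main__":
    main()
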