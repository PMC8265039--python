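#!/usr/bin/env python
"""Build the cluster-specific networks under the three edge conditions
(>1% prevalence, catalogue interaction, Spearman p < 0.05), merge them into
the regulation network and annotate TF/ligand/receptor roles."""

from pathlib import Path

from icbnet import io, networks

INPUTS = Path("scratch/synthetic_inputs")
OUT = Path("results/networks")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    matrix = io.read_expression(INPUTS / "expression.tsv")
    annotation = io.read_cell_metadata(INPUTS / "cell_metadata.tsv", matrix=matrix)
    catalog = io.read_interactions(INPUTS / "interactions.sif")
    sets_ = io.read_annotation_sets(INPUTS / "tf_list.txt", INPUTS / "lr_pairs.tsv")

    nets = networks.build_all_cluster_networks(matrix, annotation, catalog)
    merged = networks.annotate_roles(networks.merge_networks(nets), sets_)

    for net in nets:
        single = networks.annotate_roles(networks.merge_networks([net]), sets_)
        io.write_network(
            single,
            OUT / f"network_cluster{net.cluster}.sif",
            OUT / f"network_cluster{net.cluster}.nodes.tsv",
        )
    io.write_network(
        merged, OUT / "regulation_network.sif", OUT / "regulation_network.nodes.tsv"
    )
    networks.network_summary(nets).to_csv(
        OUT / "network_summary.tsv", sep="\t", index=False
    )

    roles = merged.role_counts()
    for net in nets:
        print(f"cluster {net.cluster}: {len(net.nodes)} genes, {len(net.edges)} edges")
    print(f"regulation network: {len(merged.nodes)} genes, {merged.n_edges} "
          f"interactions ({roles['ligands']} ligands, {roles['receptors']} "
          f"receptors, {roles['tfs']} TFs)")
    print(f"networks written to {OUT}/")


if __name__ == "__main__":
    main()
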