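#!/usr/bin/env python
"""Responder vs non-responder differential expression (Wilcoxon rank-sum
plus twofold change), globally and within each cluster network's gene
universe, at pre- and on-treatment."""

import importlib.util
from pathlib import Path

import pandas as pd

from icbnet import degs, io

INPUTS = Path("scratch/synthetic_inputs")
OUT = Path("results/degs")

_spec = importlib.util.spec_from_file_location(
    "topology_driver", Path(__file__).parent / "03_topology.py"
)
_mod = importlib.util.module_from_spec(_spec)
_spec.loader.exec_module(_mod)
load_cluster_networks = _mod.load_cluster_networks


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    matrix = io.read_expression(INPUTS / "expression.tsv")
    annotation = io.read_cell_metadata(INPUTS / "cell_metadata.tsv", matrix=matrix)
    nets = load_cluster_networks()

    frames = []
    for phase in ("pre", "on"):
        frames.append(degs.deg_table(degs.find_degs(matrix, annotation, phase)))
        for net in nets:
            frames.append(
                degs.deg_table(
                    degs.find_degs(
                        matrix, annotation, phase, scope=net.cluster,
                        gene_universe=sorted(net.nodes),
                    )
                )
            )
    table = pd.concat(frames, ignore_index=True)
    full_path = Path("scratch/deg_table_full.tsv")
    full_path.parent.mkdir(exist_ok=True)
    table.to_csv(full_path, sep="\t", index=False)

    sig = table[table["significant"]]
    sig.to_csv(OUT / "significant_degs.tsv", sep="\t", index=False)
    for phase in ("pre", "on"):
        glob = sig[(sig["phase"] == phase) & (sig["scope"] == "global")]
        print(f"{phase}-treatment: {len(glob)} significant genes globally "
              f"({(glob['direction'] == 'up_in_R').sum()} up in responders)")
    by_cluster = sig[sig["scope"] != "global"].groupby("scope")["gene"].nunique()
    print("within-network DEGs per cluster:",
          {k: int(v) for k, v in by_cluster.items()} if len(by_cluster) else "none")
    print(f"significant calls written to {OUT}/significant_degs.tsv; "
          f"full table in {full_path}")


if __name__ == "__main__":
    main()
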