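#!/usr/bin/env python
"""Generate the synthetic study: a typed interaction catalogue, clustered
immune cells with planted co-expression modules, responder effects and
decoy genes, TF/ligand/receptor roles, and an independent bulk cohort.

Large inputs go to scratch/synthetic_inputs/ (regenerated on demand);
the planted truth and a summary are printed.
"""

from pathlib import Path

from icbnet import io, simulate

OUT = Path("scratch/synthetic_inputs")
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    catalog = simulate.generate_pathway_catalog(seed=SEED)
    sets_ = simulate.generate_annotation_sets(catalog, seed=SEED + 1)
    matrix, annotation, truth = simulate.generate_cells(
        catalog, simulate.TruthSpec(), seed=SEED + 2, annotation_sets=sets_
    )
    bulk = simulate.generate_bulk_cohort(truth, seed=SEED + 3)

    io.write_expression(matrix, OUT / "expression.tsv")
    io.write_cell_metadata(annotation, OUT / "cell_metadata.tsv")
    io.write_interactions(catalog, OUT / "interactions.sif")
    io.write_annotation_sets(sets_, OUT / "tf_list.txt", OUT / "lr_pairs.tsv")
    io.write_bulk_cohort(bulk, OUT / "bulk_expression.tsv", OUT / "bulk_response.tsv")
    truth.to_json(OUT / "truth.json")

    n_planted = sum(len(v) for v in truth.planted_edges_per_cluster.values())
    print(f"catalogue: {len(catalog)} typed interactions, {len(catalog.genes)} genes")
    print(f"cells: {matrix.n_genes} genes x {matrix.n_cells} cells, "
          f"{annotation['cluster'].nunique()} clusters, "
          f"{annotation['sample_id'].nunique()} samples")
    print(f"planted: {n_planted} co-expression edges, "
          f"{len(truth.deg_genes)} differential genes, "
          f"{len(truth.predictive_lr_genes)} predictive ligand/receptor genes, "
          f"{len(truth.decoy_genes)} decoys at 1% prevalence")
    print(f"bulk cohort: {len(bulk.sample_ids)} samples "
          f"({bulk.response.count('R')} responders)")
    print(f"inputs written to {OUT}/")


if __name__ == "__main__":
    main()
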