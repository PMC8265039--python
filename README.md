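# icbnet

Pathway-constrained regulation networks of tumour-infiltrating immune
cells, and ligand/receptor gene-set selection for predicting response to
immune checkpoint blockade (ICB) therapy.

## The problem

Most metastatic melanoma patients do not benefit from anti-CTLA-4 /
anti-PD-1 therapy, and biomarkers that separate responders (R) from
non-responders (NR) are scarce. Single-cell RNA-seq of CD45+
tumour-infiltrating immune cells, clustered into immune cell states,
makes it possible to ask how gene regulation differs between cell states
and between R and NR patients — and whether the ligands and receptors
that sit in those regulatory networks can predict therapy outcome.

`icbnet` implements that analysis as a tested pipeline:

1. **Cluster-specific networks.** For each immune cell cluster, two genes
   are linked iff (a) each is detected in strictly more than 1% of the
   cluster's cells, (b) a pathway catalogue (extended-SIF typed gene
   pairs) records an interaction between them, and (c) the Spearman
   correlation test of their expression over those cells has p < 0.05.
   Cluster networks are merged into a single *regulation network* with
   per-edge cluster membership and TF / ligand / receptor annotation.
2. **Scale-free topology.** Each network's degree distribution is fit to
   a power law Y = aX^(−b) by ordinary least squares on
   log10 Y = −b·log10 X + log10 a; the fit's r² is reported. Cross-network
   overlap (genes and edges shared by all clusters) and the shared-core
   subnetwork are extracted.
3. **Differential expression.** Cells are split into four groups
   (pre/on treatment × R/NR); per gene, a two-sided Wilcoxon rank-sum
   p-value and a linear-scale fold change; a gene is differential when
   FC ≥ 2 (either direction) and p < 0.05.
4. **Response model.** Per-patient features are the mean expression of
   the regulation network's ligands and receptors. Repeatedly: split the
   patients into random halves, fit a logistic model with stepwise AIC
   selection on the training half, score held-out AUC on the other half.
   Unique selected gene sets are ranked by held-out AUC and occurrence,
   then re-fit on the full discovery cohort and validated on an
   independent bulk cohort (z-scored features, Mann–Whitney AUC), with
   single-gene AUC baselines.

A seeded synthetic-data generator produces all five inputs (expression,
cell metadata, interaction catalogue, TF and ligand–receptor lists, bulk
cohort) with *planted* co-expression modules, differential genes,
predictive ligand/receptor genes and 1%-prevalence decoys, so every stage
can be checked against ground truth.

## Worked example

The numbered scripts under `analysis/` run the study end-to-end on the
default synthetic inputs (500 genes, 1,200 cells, 6 clusters, 12 samples;
56-sample bulk cohort):

```sh
python analysis/01_simulate.py
python analysis/02_build_networks.py
python analysis/03_topology.py
python analysis/04_differential_expression.py
python analysis/05_response_model.py
```

`02_build_networks.py` prints, for this seed:

```
regulation network: 315 genes, 317 interactions (7 ligands, 7 receptors, 25 TFs)
```

i.e. the union of the six cluster networks, with role flags from the
TF and ligand–receptor lists. `03_topology.py` reports the power-law fits
(`b` in [2.20, 2.56], r² in [0.87, 0.96] — all six networks are
scale-free-like) and the 6 genes active in every cluster network.
`05_response_model.py` prints:

```
500 resampling iterations: median held-out AUC 1.0000 (IQR 1.000-1.000)
most-selected genes:
gene  selection_frequency  planted_predictive
G250                0.422                True
G265                0.366                True
G425                0.210                True
G500                0.002               False
```

The three genes the generator planted as response-predictive ligands/
receptors are selected far more often than any decoy, the top-ranked
gene sets validate with AUC > 0.7 on the independent bulk cohort, and the
single-gene baselines of the planted genes score AUC ≈ 0.89–0.96.

The same pipeline runs from one configuration file via the CLI
(`icbnet all --seed 1 --out results/run`), with per-stage subcommands
(`simulate`, `build-networks`, `topology`, `deg`, `select`) for resuming
long selection loops; to analyse real data, point the `inputs:` block of
the YAML configuration at your own files instead of the synthetic block.

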