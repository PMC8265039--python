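# Methods

## Model and procedure

### Cluster-specific network construction

Given a genes × cells expression matrix (log1p-scale, zeros = not
detected), per-cell cluster labels, and a typed interaction catalogue
(extended SIF: `source TAB type TAB target`), the network of cluster *k*
contains the catalogue edge (g, t, h) iff

* **prevalence** — g and h are each detected (value > 0) in *strictly
  more than* `min_fraction` (default 0.01) of the cells considered;
* **catalogue membership** — (g, t, h) is a catalogue triple;
* **co-expression** — the two-sided Spearman correlation test of g and h
  over cluster *k*'s cells has p < `edge_alpha` (default 0.05).

The prevalence denominator is ambiguous in principle (all cells vs the
cluster's cells); the default is the cluster's own cells, consistent with
the cluster-specific correlation condition, and `prevalence_scope:
global` switches to the whole population. Spearman uses average ranks for
ties and the t approximation for p (identical to scipy's `spearmanr`);
the network builder ranks the cluster submatrix once and evaluates all
candidate pairs as Pearson correlations of rank vectors, which a test
verifies against the scalar path to 1e-12. A constant expression vector
makes the correlation undefined: the pair is scored (rho = NaN, p = 1)
and therefore never linked. Directed interaction types keep their
direction; complex-membership types (`in-complex-with`,
`interacts-with`) are canonicalized to lexicographic endpoint order so an
undirected edge is stored once. Edge p-values are *not*
multiple-testing-corrected (raw p < 0.05 is the construction rule);
isolated nodes cannot occur since nodes exist only through retained
edges.

Cluster networks merge by edge-key union; each edge and node carries the
set of contributing clusters. Roles (TF, ligand, receptor) are set
membership against the TF list and the first/second columns of the
ligand–receptor pair list; a gene may hold several roles.

### Topology

Degree ignores direction; parallel edges of different types count as
distinct incidences because edges are typed objects throughout. The
degree distribution (degree X, fraction of nodes Y) is fit by OLS of
log10 Y on log10 X, giving Y = aX^(−b) with a = 10^intercept,
b = −slope, and the regression r². No low-degree points are excluded by
default and no logarithmic binning is applied; the fit requires at least
three distinct degrees. r² is reported, not thresholded — scale-freeness
is a descriptive claim. Overlap statistics are exact set intersections on
node ids and typed edge keys; the shared-core subnetwork keeps edges
whose membership set covers all clusters.

### Differential expression

Within one phase (pre/on), responder and non-responder cells are
compared per gene by a two-sided Wilcoxon rank-sum test (exact for small
tie-free groups, tie-corrected normal approximation with continuity
correction otherwise — R's `wilcox.test` behaviour). The fold change is
defined on the linear scale under the log1p data contract with a
pseudo-count of 1:

    FC = (mean(expm1(x_R)) + 1) / (mean(expm1(x_NR)) + 1)

A gene is called differential when (FC ≥ 2 or FC ≤ 0.5) and p < 0.05.
The pseudo-count bounds the FC of weakly expressed genes toward 1, so
twofold calls require mean linear expression ≳ 2; this is a declared
convention, not an inference. Cluster-scope tests use the cluster
network's genes as the universe; the global scope uses all matrix genes.

### Response model

Patient-level features are per-sample means over the sample's cells
(alternatives considered: median, fraction-positive; the mean is the
default because the downstream logistic model is linear in the features).
The feature panel is the regulation network's ligands ∪ receptors. The
discovery phase pools pre- and on-treatment cells by default
(`feature_phase` selects one phase).

Each resampling iteration: (1) a uniform random half/half patient split,
redrawn until the training half has ≥ 2 patients of each class and the
test half has both classes (requirements relax automatically when class
counts make them infeasible, e.g. a singleton class); (2) a logistic fit
with greedy stepwise AIC selection — each round refits every single
add/drop neighbour of the current model and accepts the largest AIC
decrease, stopping at a local minimum, ties broken by feature order;
(3) held-out AUC (Mann–Whitney form: P(score_R > score_NR) + ½P(tie)).
Per-iteration seeds spawn from one base seed, making the whole run list
bit-reproducible. Selected gene sets are deduplicated by unordered
composition and ranked by best held-out AUC, then occurrence count
(`max_sets` defaults to 17). Validation refits each ranked set on the
full discovery cohort with per-cohort z-scored features and applies the
linear predictor to the z-scored bulk cohort; z-scoring bridges the
single-cell-aggregate vs bulk platform difference. A gene set with any
member absent from the bulk cohort is reported and skipped.

Logistic fitting is Newton scoring (IRLS) on the binomial likelihood.
The selection loop performs on the order of 10^5–10^6 fits on matrices
with tens of rows, so the solver is a compact numpy implementation; a
unit test pins its coefficients and AIC to statsmodels GLM at 1e-6.
Separation (non-convergence or saturated linear predictor) triggers a
ridge fallback with penalty 1e-4 on the standardized-feature scale,
flagged in the result; during stepwise move evaluation the ridge refit is
skipped because the separated fit's log-likelihood is already at its
supremum to numerical precision, which is all the AIC comparison needs —
only the final selected model is stabilized for prediction. The stepwise
search starts from the empty model by default (`stepwise_start: full`
starts from the full panel); with few patients the full model is
saturated and every start degenerates to the penalized fit, whereas the
forward/both search from the null model is well-defined at any size.

## Synthetic data: what it emulates, and what it does not

The generator produces the five pipeline inputs with known structure:

* **catalogue** — a Barabási–Albert preferential-attachment graph
  (default 500 genes, mean degree 4), each edge typed uniformly from a
  13-type vocabulary and randomly oriented, giving the heavy-tailed
  degree distribution real pathway databases show.
* **cells** — counts are Poisson with log-normal rate heterogeneity
  (log-rate noise SD 0.3, an overdispersed NB-like marginal); stored
  values are log1p(counts). Defaults: 1,200 cells, 6 clusters, 12
  samples (half R / half NR, each half split pre/on treatment).
* **planted co-expression modules** — per cluster, 4 modules of 5
  catalogue-adjacent genes share a Gaussian latent factor added to the
  log-rate of that cluster's cells, with loading set so the latent
  log-rate correlation equals `module_rho` (default 0.6); all catalogue
  edges inside a module are "planted" for that cluster. Module genes get
  a baseline floor of 5 mean counts so detection is not limiting.
* **planted differential genes** — 10 genes per phase receive a 2.5-fold
  rate shift in responder cells of that phase (random direction), with a
  baseline floor of 10 mean counts so the twofold gate is decidable
  above the pseudo-count. Three of them — the **predictive genes** — are
  drawn from the ligand/receptor lists, shifted upward in responders in
  *both* phases, and anchored by a two-gene co-expression module on a
  catalogue neighbour so they reliably reach the regulation network's
  feature panel.
* **decoys** — 10 genes detected in exactly floor(1% · n_cells) cells,
  constructed rather than sampled, so the strict >1% prevalence filter
  must remove every one.
* **bulk cohort** — 56 samples (22 responders, mirroring a typical
  validation cohort), per-gene values = population log-mean + the
  predictive genes' pooled log-fold effect in responders + N(0, 0.5)
  noise.

Deliberately *not* emulated: library-size variation, batch and
sample-level random effects, ambient RNA, doublets, dropout beyond the
decoy construction, and gene-length/GC effects. Because cells are
conditionally independent given their cluster and response labels, the
edge test is exactly calibrated here; in real data, sample-level
pseudo-replication can inflate within-cluster correlations, so passing
the null-calibration tests says the *statistics* are correct, not that
real-data edges are immune to confounding.

## Test and problem sizes

The default synthetic sizes (500 × 1,200, 6 clusters, 12 samples) keep a
full pipeline run in seconds and the Monte-Carlo acceptance checks
(100 independent draws; 100 replicates of a 500-iteration selection
loop) in minutes on one CPU. The selection loop defaults to 500
iterations in scripted analyses; the procedure supports arbitrary
`n_iter` (the original-scale choice would be 10,000) at linear cost.

## Numerical choices and degenerate inputs

* Spearman p from the t approximation at all n; |rho| = 1 maps to p = 0.
* Wilcoxon on two all-zero groups returns (FC 1, p 1) by contract, as
  does any constant pooled sample.
* AIC counts the intercept; the empty (intercept-only) model is the
  stepwise baseline.
* Constant feature columns are dropped from logistic fits with a
  warning; a zero-variance bulk feature is an error naming the gene.
* Duplicate gene rows in expression input collapse to the row with the
  highest total (the choice is logged); gene symbols are upper-cased and
  matched exactly across all inputs.
* Catalogue genes absent from the expression matrix simply fail the
  prevalence condition.
* All generators and the selection loop derive per-draw seeds from a
  single SeedSequence, and the pipeline writes a checksum manifest, so a
  re-run under the same configuration and seed is byte-identical.

## Known limitations

* The log-log OLS power-law fit is the classical descriptive check; it
  is not a maximum-likelihood tail fit and r² > 0.8 should not be read
  as a goodness-of-fit test.
* With very few patients, held-out AUC on 6-sample halves is extremely
  granular, and a fixed small cohort with many features can contain an
  accidentally separating feature in both halves; interpretation of the
  median held-out AUC requires samples ≫ informative features.
* The 17-set cap on ranked gene sets is a reporting convention; the
  ranking rule (best held-out AUC, then occurrence) is explicit but not
  the only defensible one.
* Probe-to-symbol mapping for microarray bulk cohorts is out of scope;
  the loader expects symbol-level input.
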