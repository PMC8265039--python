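"""Resampling logistic-regression selection of ligand/receptor gene sets.

The procedure mirrors repeated random subsampling validation:

1. aggregate cells to per-sample features (mean expression of each ligand
   and receptor in the regulation network);
2. split the samples into random halves, fit a logistic model on the
   training half and run stepwise AIC selection over the feature panel;
3. score the selected model's AUC on the held-out half;
4. repeat; rank the unique selected gene sets by held-out AUC and
   occurrence, then validate the top sets on an independent bulk cohort.

Logistic models are fit by iteratively reweighted least squares (IRLS,
i.e. Newton scoring on the binomial log-likelihood). The selection loop
performs millions of fits on matrices with tens of rows, so the solver is
a tight numpy implementation; on detected separation or non-convergence it
falls back to a small ridge penalty (flagged in the result). A unit test
cross-checks coefficients against statsmodels GLM.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .io import BulkCohort, ExpressionMatrix
from .networks import RegulationNetwork

logger = logging.getLogger("icbnet")

RIDGE_FALLBACK = 1e-4  # penalty used when the ML fit separates
MAX_ABS_COEF = 15.0  # |beta| beyond this on standardized-ish features => separation


# ---------------------------------------------------------------------------
# feature table


@dataclass
class PatientFeatureTable:
    sample_ids: list[str]
    genes: list[str]
    values: np.ndarray  # (n_samples, n_genes)
    response: list[str]  # "R"/"NR"

    @property
    def y(self) -> np.ndarray:
        return np.array([1 if r == "R" else 0 for r in self.response])

    def columns(self, genes: Sequence[str]) -> np.ndarray:
        idx = {g: i for i, g in enumerate(self.genes)}
        return self.values[:, [idx[g] for g in genes]]

    def subset_samples(self, sample_ids: Sequence[str]) -> "PatientFeatureTable":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [idx[s] for s in sample_ids]
        return PatientFeatureTable(
            sample_ids=list(sample_ids),
            genes=list(self.genes),
            values=self.values[rows],
            response=[self.response[i] for i in rows],
        )


def build_feature_table(
    matrix: ExpressionMatrix,
    annotation: pd.DataFrame,
    regulation_network: RegulationNetwork,
    phase: str = "pooled",
) -> PatientFeatureTable:
    """Per-sample mean expression of the network's ligand and receptor genes.

    *phase* restricts to pre- or on-treatment cells ("pooled" uses all). A
    feature gene absent from the matrix becomes an all-zero column with a
    warning, preserving the declared feature panel.
    """
    panel = sorted(
        regulation_network.genes_with_role("ligand")
        | regulation_network.genes_with_role("receptor")
    )
    if not panel:
        raise ValueError("regulation network has no annotated ligands/receptors")
    ann = annotation if phase == "pooled" else annotation[annotation["phase"] == phase]
    samples = sorted(ann["sample_id"].unique())
    if not samples:
        raise ValueError(f"no samples with cells in phase {phase!r}")
    missing = [g for g in panel if g not in matrix._gene_index]
    if missing:
        logger.warning("feature genes absent from matrix -> zero column: %s", missing)
    values = np.zeros((len(samples), len(panel)))
    response = []
    for i, s in enumerate(samples):
        cells = ann.loc[ann["sample_id"] == s, "cell_id"].tolist()
        if not cells:
            raise ValueError(f"sample {s!r} has no cells")
        sub = matrix.cell_columns(cells)
        means = sub.mean(axis=1)
        for j, g in enumerate(panel):
            if g in matrix._gene_index:
                values[i, j] = means[matrix._gene_index[g]]
        response.append(ann.loc[ann["sample_id"] == s, "response"].iloc[0])
    return PatientFeatureTable(
        sample_ids=samples, genes=panel, values=values, response=response
    )


# ---------------------------------------------------------------------------
# splitting


def split_half(
    samples: Sequence[str],
    labels: Sequence[str],
    seed: int,
    max_retries: int = 1000,
    min_class_train: int = 1,
) -> tuple[list[str], list[str]]:
    """Random half/half split with both classes in both halves.

    An odd sample count puts the extra sample in the training half. Splits
    violating the class constraint (at least *min_class_train* samples of
    each class in the training half, at least one of each in the test half)
    are redrawn up to *max_retries* times.
    """
    if len(samples) < 4:
        raise ValueError("need >= 4 samples to split")
    if len(set(labels)) < 2:
        raise ValueError("both classes must be present")
    rng = np.random.default_rng(seed)
    n_train = (len(samples) + 1) // 2
    lab = dict(zip(samples, labels))
    classes = sorted(set(labels))
    totals = {c: sum(l == c for l in labels) for c in classes}
    # per-class requirements, relaxed to what the class counts allow
    # (a singleton class cannot be in both halves)
    req_train = {
        c: min(min_class_train, max(totals[c] - 1, 0)) for c in classes
    }
    req_test = {
        c: 1 if totals[c] - req_train[c] >= 1 and totals[c] > 1 else 0
        for c in classes
    }
    for _ in range(max_retries):
        perm = rng.permutation(len(samples))
        train = [samples[i] for i in perm[:n_train]]
        test = [samples[i] for i in perm[n_train:]]
        ok = all(
            sum(lab[s] == c for s in train) >= req_train[c]
            and sum(lab[s] == c for s in test) >= req_test[c]
            for c in classes
        )
        if ok:
            return train, test
    raise RuntimeError(f"no class-balanced split found in {max_retries} retries")


# ---------------------------------------------------------------------------
# logistic fitting (IRLS with ridge fallback)


@dataclass
class LogisticFit:
    genes: list[str]
    coefficients: np.ndarray  # per-gene
    intercept: float
    loglik: float  # unpenalized log-likelihood at the fitted parameters
    aic: float
    converged: bool
    ridged: bool
    dropped: list[str] = field(default_factory=list)  # constant columns removed

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Probability of response for rows of X (columns = self.genes)."""
        return expit(self.linear_predictor(X))

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.coefficients + self.intercept


def _irls(
    X: np.ndarray, y: np.ndarray, ridge: float | np.ndarray = 0.0,
    max_iter: int = 30, tol: float = 1e-10,
) -> tuple[np.ndarray, bool]:
    """Newton scoring for logistic regression; X includes the intercept column.

    The ridge penalty (never on the intercept) stabilizes separated fits.
    Unpenalized fits bail out early once the linear predictor saturates
    (|eta| > 30), the signature of separation. Returns (beta, converged).
    """
    n, p = X.shape
    beta = np.zeros(p)
    pen = np.broadcast_to(np.asarray(ridge, dtype=float), (p,)).copy()
    pen[0] = 0.0
    penalized = bool(pen.any())
    diag = np.diag(pen)
    prev_ll = -np.inf
    for _ in range(max_iter):
        eta = X @ beta
        if not penalized and np.abs(eta).max() > 20.0:
            return beta, False
        mu = expit(eta)
        w = np.maximum(mu * (1.0 - mu), 1e-12)
        grad = X.T @ (y - mu) - pen * beta
        H = (X.T * w) @ X + diag
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            return beta, False
        beta = beta + step
        eta = X @ beta
        ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
        if penalized:
            ll -= 0.5 * float(pen @ beta**2)
        if abs(ll - prev_ll) < tol:
            return beta, True
        prev_ll = ll
    return beta, False


def _loglik(X: np.ndarray, y: np.ndarray, beta: np.ndarray) -> float:
    eta = X @ beta
    # numerically stable: -log(1 + exp(-|eta|)) formulation
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_logistic(
    features: np.ndarray,
    labels: np.ndarray,
    genes: Sequence[str] | None = None,
    ridge_refit: bool = True,
) -> LogisticFit:
    """Maximum-likelihood logistic fit; ridge fallback on separation.

    *labels* are 0/1 (1 = responder). Constant feature columns are dropped
    with a warning. The AIC uses the unpenalized log-likelihood and counts
    the intercept as a parameter. With ``ridge_refit=False`` a separated
    fit is returned as-is (flagged not converged) instead of being refit
    under the ridge penalty — the log-likelihood, and hence the AIC, is
    already at its supremum to numerical precision when the fit separates,
    so criterion-based selection does not need the stabilized coefficients.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(labels, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("labels must be 0/1")
    if y.sum() < 2 or (1 - y).sum() < 2:
        raise ValueError("need >= 2 samples per class")
    genes = list(genes) if genes is not None else [f"x{i}" for i in range(X.shape[1])]
    keep = [j for j in range(X.shape[1]) if np.ptp(X[:, j]) > 0]
    dropped = [genes[j] for j in range(X.shape[1]) if j not in keep]
    if dropped:
        logger.warning("dropping constant feature columns: %s", dropped)
    Xk = X[:, keep]
    genes_k = [genes[j] for j in keep]
    Xd = np.column_stack([np.ones(len(y)), Xk])

    beta, converged = _irls(Xd, y)
    ridged = False
    scale = np.abs(Xd).max(axis=0)
    scale[scale == 0] = 1.0
    separated = not converged or np.any(np.abs(beta * scale) > MAX_ABS_COEF)
    if separated and ridge_refit:
        # penalty expressed on the standardized-feature scale
        sd = Xd.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        beta, converged = _irls(Xd, y, ridge=RIDGE_FALLBACK * sd**2)
        ridged = True
    ll = _loglik(Xd, y, beta)
    k = Xd.shape[1]
    return LogisticFit(
        genes=genes_k,
        coefficients=beta[1:],
        intercept=float(beta[0]),
        loglik=ll,
        aic=float(-2.0 * ll + 2.0 * k),
        converged=converged,
        ridged=ridged,
        dropped=dropped,
    )


# ---------------------------------------------------------------------------
# stepwise AIC selection


def stepwise_select(
    features: np.ndarray,
    labels: np.ndarray,
    genes: Sequence[str],
    start_model: Sequence[str] = (),
    direction: str = "both",
    criterion: str = "aic",
) -> tuple[list[str], LogisticFit]:
    """Greedy add/drop selection minimizing the AIC of a logistic model.

    Each round refits every single-change neighbour of the current model
    and accepts the change with the largest AIC decrease; the search stops
    at a local minimum. Ties break by feature-list order, making the
    procedure deterministic given the input order.
    """
    if criterion != "aic":
        raise ValueError("only the AIC criterion is supported")
    if direction not in {"both", "forward", "backward"}:
        raise ValueError(f"unknown direction {direction!r}")
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=float)
    genes = list(genes)
    gene_idx = {g: i for i, g in enumerate(genes)}
    current = [g for g in genes if g in set(start_model)]

    def fit_subset(subset: list[str], ridge_refit: bool = False) -> LogisticFit:
        if subset:
            return fit_logistic(
                X[:, [gene_idx[g] for g in subset]], y,
                genes=subset, ridge_refit=ridge_refit,
            )
        return fit_logistic(np.empty((len(y), 0)), y, genes=[])

    best_fit = fit_subset(current)
    while True:
        moves: list[tuple[float, list[str], LogisticFit]] = []
        if direction in {"both", "backward"}:
            for g in current:
                cand = [h for h in current if h != g]
                fit = fit_subset(cand)
                moves.append((fit.aic, cand, fit))
        if direction in {"both", "forward"}:
            in_model = set(current)
            for g in genes:
                if g not in in_model:
                    cand = current + [g]
                    fit = fit_subset(cand)
                    moves.append((fit.aic, cand, fit))
        if not moves:
            break
        best_aic, best_cand, best_move_fit = min(moves, key=lambda m: m[0])
        if best_aic < best_fit.aic - 1e-12:
            current = best_cand
            best_fit = best_move_fit
        else:
            break
    if not best_fit.converged:
        best_fit = fit_subset(current, ridge_refit=True)
    return current, best_fit


# ---------------------------------------------------------------------------
# AUC


def auc(scores: Sequence[float], labels: Sequence[str] | np.ndarray) -> float:
    """Mann-Whitney AUC: P(score_R > score_NR) + 0.5 P(tie)."""
    scores = np.asarray(scores, dtype=float)
    y = _binary_labels(labels)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(scores)
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def _binary_labels(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "if":
        return arr.astype(int)
    return np.array([1 if str(v) == "R" else 0 for v in arr])


# ---------------------------------------------------------------------------
# the selection loop


@dataclass
class SelectionRun:
    iteration: int
    seed: int
    train_samples: list[str]
    test_samples: list[str]
    selected_genes: list[str]
    coefficients: dict[str, float]
    intercept: float
    ridged: bool
    train_auc: float
    test_auc: float


def run_selection_loop(
    feature_table: PatientFeatureTable,
    n_iter: int = 10_000,
    base_seed: int = 0,
    direction: str = "both",
    start: str = "empty",
) -> tuple[list[SelectionRun], dict]:
    """Repeat split / fit / stepwise-select / held-out-AUC *n_iter* times.

    Per-iteration seeds derive from *base_seed* through a SeedSequence, so
    the whole run list is reproducible bit for bit. *start* chooses the
    stepwise starting model: "empty" (null model) or "full" (all features).
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    ss = np.random.SeedSequence(base_seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_iter)]
    y_lookup = dict(zip(feature_table.sample_ids, feature_table.response))
    runs: list[SelectionRun] = []
    start_model = list(feature_table.genes) if start == "full" else []
    for it in range(n_iter):
        seed = seeds[it]
        train_ids, test_ids = split_half(
            feature_table.sample_ids, feature_table.response, seed,
            min_class_train=2,
        )
        assert not set(train_ids) & set(test_ids)  # anti-leakage
        train = feature_table.subset_samples(train_ids)
        test = feature_table.subset_samples(test_ids)
        selected, fit = stepwise_select(
            train.values, train.y, train.genes,
            start_model=start_model, direction=direction,
        )
        if selected:
            train_scores = fit.predict(train.columns(selected))
            test_scores = fit.predict(test.columns(selected))
        else:  # intercept-only model scores everyone identically
            train_scores = np.full(len(train_ids), 0.5)
            test_scores = np.full(len(test_ids), 0.5)
        runs.append(
            SelectionRun(
                iteration=it,
                seed=seed,
                train_samples=train_ids,
                test_samples=test_ids,
                selected_genes=selected,
                coefficients=dict(zip(fit.genes, fit.coefficients.tolist())),
                intercept=fit.intercept,
                ridged=fit.ridged,
                train_auc=auc(train_scores, [y_lookup[s] for s in train_ids]),
                test_auc=auc(test_scores, [y_lookup[s] for s in test_ids]),
            )
        )
    test_aucs = np.array([r.test_auc for r in runs])
    freq: dict[str, float] = {g: 0.0 for g in feature_table.genes}
    for r in runs:
        for g in r.selected_genes:
            freq[g] += 1.0 / n_iter
    summary = {
        "n_iter": n_iter,
        "median_test_auc": float(np.median(test_aucs)),
        "q25_test_auc": float(np.quantile(test_aucs, 0.25)),
        "q75_test_auc": float(np.quantile(test_aucs, 0.75)),
        "selection_frequency": freq,
    }
    return runs, summary


def rank_gene_sets(runs: Sequence[SelectionRun], max_sets: int = 17) -> pd.DataFrame:
    """Deduplicate selected gene sets and rank by best held-out AUC, then
    occurrence count. Empty selections are excluded."""
    if not runs:
        raise ValueError("need >= 1 run")
    groups: dict[frozenset, list[SelectionRun]] = {}
    for r in runs:
        if r.selected_genes:
            groups.setdefault(frozenset(r.selected_genes), []).append(r)
    rows = []
    for gene_set, members in groups.items():
        aucs = [m.test_auc for m in members]
        rows.append(
            {
                "genes": ",".join(sorted(gene_set)),
                "n_genes": len(gene_set),
                "count": len(members),
                "best_test_auc": max(aucs),
                "median_test_auc": float(np.median(aucs)),
            }
        )
    df = pd.DataFrame(rows).sort_values(
        ["best_test_auc", "count", "genes"], ascending=[False, False, True]
    )
    return df.head(max_sets).reset_index(drop=True)


# ---------------------------------------------------------------------------
# external validation


@dataclass
class FittedGeneSetModel:
    genes: list[str]
    coefficients: dict[str, float]
    intercept: float
    discovery_auc: float
    validation_auc: float
    validation_scores: list[float] = field(default_factory=list)


def _zscore(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    if np.any(sd == 0):
        raise ValueError("zero-variance feature column")
    return (X - mu) / sd


def validate_external(
    gene_set: Sequence[str],
    discovery_table: PatientFeatureTable,
    bulk_cohort: BulkCohort,
) -> FittedGeneSetModel:
    """Refit a gene set on the full discovery cohort and score it on the bulk
    cohort. Features are z-scored within each cohort independently to bridge
    the platform difference."""
    genes = list(gene_set)
    if not genes:
        raise ValueError("empty gene set")
    missing = [g for g in genes if g not in bulk_cohort._gene_index]
    if missing:
        raise KeyError(f"genes absent from bulk cohort: {missing}")
    Xd = _zscore(discovery_table.columns(genes))
    fit = fit_logistic(Xd, discovery_table.y, genes=genes)
    disc_auc = auc(fit.predict(Xd), discovery_table.response)
    Xb = np.column_stack([bulk_cohort.gene_column(g) for g in genes])
    sd = Xb.std(axis=0, ddof=0)
    if np.any(sd == 0):
        bad = genes[int(np.argmax(sd == 0))]
        raise ValueError(f"degenerate (zero-variance) bulk feature: {bad}")
    coef = np.array([dict(zip(fit.genes, fit.coefficients))[g] for g in fit.genes])
    scores = _zscore(Xb)[:, [genes.index(g) for g in fit.genes]] @ coef + fit.intercept
    val_auc = auc(scores, bulk_cohort.response)
    return FittedGeneSetModel(
        genes=genes,
        coefficients=dict(zip(fit.genes, fit.coefficients.tolist())),
        intercept=fit.intercept,
        discovery_auc=disc_auc,
        validation_auc=val_auc,
        validation_scores=scores.tolist(),
    )


def roc_points(scores, labels) -> pd.DataFrame:
    """ROC curve points (threshold, fpr, tpr) for one score vector."""
    scores = np.asarray(scores, dtype=float)
    y = _binary_labels(labels)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    order = np.argsort(-scores, kind="stable")
    rows = [{"threshold": np.inf, "fpr": 0.0, "tpr": 0.0}]
    tp = fp = 0
    prev = None
    for i in order:
        if prev is not None and scores[i] != prev:
            rows.append({"threshold": prev, "fpr": fp / n0, "tpr": tp / n1})
        tp += int(y[i] == 1)
        fp += int(y[i] == 0)
        prev = scores[i]
    rows.append({"threshold": prev, "fpr": fp / n0, "tpr": tp / n1})
    return pd.DataFrame(rows)


def single_gene_auc(gene: str, bulk_cohort: BulkCohort) -> float:
    """AUC of one gene's raw expression as the response score."""
    return auc(bulk_cohort.gene_column(gene), bulk_cohort.response)
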