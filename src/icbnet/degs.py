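"""Responder vs non-responder differential expression.

Cells are stratified into four groups (pre/on treatment x R/NR). For a
given phase, each gene is scored by a two-sided Wilcoxon rank-sum test and
a linear-scale fold change; a gene is called differentially expressed when
the fold change is at least twofold (either direction) and p < 0.05.

Expression values are log1p-scale by data contract, so the fold change is
computed after inverting the transform, with a pseudo-count of 1:

    FC = (mean(expm1(R)) + 1) / (mean(expm1(NR)) + 1)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix


@dataclass
class DEGRecord:
    gene: str
    phase: str  # "pre" | "on"
    scope: str  # "global" | "cluster <k>"
    fold_change: float  # linear-scale R over NR
    p_value: float
    direction: str  # "up_in_R" | "up_in_NR"
    significant: bool


def group_cells(
    annotation: pd.DataFrame, phase: str, scope: str | int = "global"
) -> tuple[list[str], list[str]]:
    """Split the cells of one phase (and optionally one cluster) into
    responder and non-responder lists."""
    if phase not in {"pre", "on"}:
        raise ValueError(f"phase must be 'pre' or 'on', got {phase!r}")
    mask = annotation["phase"] == phase
    if scope != "global":
        mask &= annotation["cluster"] == int(scope)
    sub = annotation[mask]
    r_cells = sub.loc[sub["response"] == "R", "cell_id"].tolist()
    nr_cells = sub.loc[sub["response"] == "NR", "cell_id"].tolist()
    stratum = f"phase={phase}, scope={scope}"
    if not r_cells:
        raise ValueError(f"no responder cells in stratum ({stratum})")
    if not nr_cells:
        raise ValueError(f"no non-responder cells in stratum ({stratum})")
    return r_cells, nr_cells


def test_gene(
    values_r: np.ndarray, values_nr: np.ndarray
) -> tuple[float, float]:
    """Fold change and two-sided Wilcoxon rank-sum p for one gene.

    The rank-sum p is exact for small tie-free groups and otherwise uses
    the tie-corrected normal approximation with continuity correction
    (matching R's ``wilcox.test`` defaults). Two all-zero groups return
    (1.0, 1.0) by contract.
    """
    values_r = np.asarray(values_r, dtype=float)
    values_nr = np.asarray(values_nr, dtype=float)
    if len(values_r) < 3 or len(values_nr) < 3:
        raise ValueError("need >= 3 values per group")
    fc = (np.expm1(values_r).mean() + 1.0) / (np.expm1(values_nr).mean() + 1.0)
    if not values_r.any() and not values_nr.any():
        return (1.0, 1.0)
    pooled = np.concatenate([values_r, values_nr])
    if np.ptp(pooled) == 0:  # constant data: rank-sum test undefined
        return (float(fc), 1.0)
    res = stats.mannwhitneyu(values_r, values_nr, alternative="two-sided")
    return (float(fc), float(res.pvalue))


def find_degs(
    matrix: ExpressionMatrix,
    annotation: pd.DataFrame,
    phase: str,
    scope: str | int = "global",
    fc_threshold: float = 2.0,
    alpha: float = 0.05,
    gene_universe: list[str] | None = None,
) -> list[DEGRecord]:
    """Score every gene of the universe for the R-vs-NR contrast.

    *gene_universe* defaults to all matrix genes; for cluster scope the
    caller usually passes the cluster network's genes. One record per gene,
    sorted by p-value.
    """
    r_cells, nr_cells = group_cells(annotation, phase, scope)
    if gene_universe is None:
        gene_universe = list(matrix.gene_ids)
    r_idx = [matrix._cell_index[c] for c in r_cells]
    nr_idx = [matrix._cell_index[c] for c in nr_cells]
    scope_str = "global" if scope == "global" else f"cluster {scope}"
    records = []
    for gene in gene_universe:
        row = matrix.gene_row(gene)
        fc, p = test_gene(row[r_idx], row[nr_idx])
        sig = (fc >= fc_threshold or fc <= 1.0 / fc_threshold) and p < alpha
        records.append(
            DEGRecord(
                gene=gene,
                phase=phase,
                scope=scope_str,
                fold_change=fc,
                p_value=p,
                direction="up_in_R" if fc >= 1.0 else "up_in_NR",
                significant=bool(sig),
            )
        )
    records.sort(key=lambda r: (r.p_value, r.gene))
    return records


def deg_table(records: list[DEGRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": [r.gene for r in records],
            "phase": [r.phase for r in records],
            "scope": [r.scope for r in records],
            "fold_change": [r.fold_change for r in records],
            "p_value": [r.p_value for r in records],
            "direction": [r.direction for r in records],
            "significant": [r.significant for r in records],
        }
    )
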