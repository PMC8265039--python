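"""Readers and writers for every external format the pipeline touches.

All files are UTF-8, tab-separated text; lines starting with ``#`` are
ignored. Gene identifiers are HGNC-style symbols, upper-cased and matched
by exact string across all inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("icbnet")

PHASE_TOKENS = {
    "pre": "pre",
    "pre-treatment": "pre",
    "pretreatment": "pre",
    "baseline": "pre",
    "on": "on",
    "on-treatment": "on",
    "ontreatment": "on",
    "post": "on",
    "post-treatment": "on",
}
RESPONSE_TOKENS = {
    "r": "R",
    "responder": "R",
    "response": "R",
    "nr": "NR",
    "non-responder": "NR",
    "nonresponder": "NR",
    "non_responder": "NR",
}

METADATA_COLUMNS = ("cell_id", "cluster", "sample_id", "phase", "response")


class DataError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class ExpressionMatrix:
    """A genes x cells matrix of non-negative log-scale expression values.

    Zeros mean "transcript not detected"; the prevalence filter of the
    network stage counts strictly positive entries.
    """

    gene_ids: list[str]
    cell_ids: list[str]
    values: np.ndarray  # shape (n_genes, n_cells)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise DataError(
                f"value shape {self.values.shape} inconsistent with "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise DataError("duplicate gene ids")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise DataError("duplicate cell ids")
        if self.values.size and self.values.min() < 0:
            g, c = np.unravel_index(int(np.argmin(self.values)), self.values.shape)
            raise DataError(
                f"negative value at gene {self.gene_ids[g]!r}, cell {self.cell_ids[c]!r}"
            )
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}
        self._cell_index = {c: i for i, c in enumerate(self.cell_ids)}

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def gene_row(self, gene: str) -> np.ndarray:
        if gene not in self._gene_index:
            raise KeyError(f"gene {gene!r} not in matrix")
        return self.values[self._gene_index[gene]]

    def cell_columns(self, cells: Sequence[str]) -> np.ndarray:
        idx = [self._cell_index[c] for c in cells]
        return self.values[:, idx]

    def submatrix(self, cells: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(
            list(self.gene_ids), list(cells), self.cell_columns(cells)
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_ids)


@dataclass
class PathwayInteractionSet:
    """Typed, directed gene-pair catalogue constraining candidate edges."""

    records: list[tuple[str, str, str]]  # (source, interaction_type, target)

    def __post_init__(self) -> None:
        seen = set(self.records)
        if len(seen) != len(self.records):
            raise DataError("duplicate (source, type, target) triples")
        for s, t, o in self.records:
            if s == o:
                raise DataError(f"self-loop retained: {s} {t} {o}")

    @property
    def types(self) -> set[str]:
        return {t for _, t, _ in self.records}

    @property
    def genes(self) -> set[str]:
        out: set[str] = set()
        for s, _, o in self.records:
            out.add(s)
            out.add(o)
        return out

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


@dataclass
class AnnotationSets:
    """Transcription-factor, ligand and receptor role assignments."""

    tfs: set[str]
    lr_pairs: set[tuple[str, str]]
    ligands: set[str] = field(init=False)
    receptors: set[str] = field(init=False)

    def __post_init__(self) -> None:
        self.ligands = {l for l, _ in self.lr_pairs}
        self.receptors = {r for _, r in self.lr_pairs}


@dataclass
class BulkCohort:
    """Bulk validation cohort: samples x genes expression plus R/NR labels."""

    sample_ids: list[str]
    gene_ids: list[str]
    values: np.ndarray  # (n_samples, n_genes)
    response: list[str]  # "R"/"NR" per sample

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.gene_ids)):
            raise DataError("bulk value shape inconsistent with ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise DataError("duplicate bulk sample ids")
        if len(self.response) != len(self.sample_ids):
            raise DataError("response label missing for some samples")
        bad = sorted(set(self.response) - {"R", "NR"})
        if bad:
            raise DataError(f"unknown response labels: {bad}")
        if len(set(self.response)) < 2:
            raise DataError("bulk cohort must contain both response classes")
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}

    def gene_column(self, gene: str) -> np.ndarray:
        if gene not in self._gene_index:
            raise KeyError(f"gene {gene!r} not in bulk cohort")
        return self.values[:, self._gene_index[gene]]


# ---------------------------------------------------------------------------
# expression


def read_expression(path: str | Path, format: str = "tsv") -> ExpressionMatrix:
    """Load a genes x cells matrix from TSV or MatrixMarket triplet form.

    For ``format="mtx"``, *path* points to the ``.mtx`` file and two sibling
    index files ``<stem>.genes.txt`` / ``<stem>.cells.txt`` hold the row and
    column identifiers, one per line.

    Duplicate gene symbols are collapsed by keeping the row with the highest
    total expression; the collapse is logged.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        # pandas mangles duplicate column names, so check the raw header
        with open(path, encoding="utf-8") as fh:
            header = next(
                (ln for ln in fh if ln.strip() and not ln.startswith("#")), ""
            )
        header_cells = header.rstrip("\n").split("\t")[1:]
        if len(set(header_cells)) != len(header_cells):
            dup = next(c for c in header_cells if header_cells.count(c) > 1)
            raise DataError(f"duplicate cell id {dup!r} in {path}")
        df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
        genes = [str(g).strip().upper() for g in df.index]
        values = df.to_numpy(dtype=float)
        cells = [str(c) for c in df.columns]
    elif format == "mtx":
        from scipy.io import mmread

        mat = mmread(path)
        genes = _read_lines(path.with_suffix("").with_suffix(".genes.txt"))
        cells = _read_lines(path.with_suffix("").with_suffix(".cells.txt"))
        genes = [g.upper() for g in genes]
        values = np.asarray(mat.todense() if hasattr(mat, "todense") else mat, dtype=float)
    else:
        raise ValueError(f"unknown expression format {format!r}")

    if np.isnan(values).any():
        raise DataError(f"malformed (non-numeric) entries in {path}")
    if values.size and values.min() < 0:
        gi, ci = np.unravel_index(int(np.argmin(values)), values.shape)
        raise DataError(
            f"negative value in {path} at row {genes[gi]!r}, column {ci}"
        )

    # collapse duplicate gene symbols: keep the row with the highest total
    if len(set(genes)) != len(genes):
        totals = values.sum(axis=1)
        keep: dict[str, int] = {}
        for i, g in enumerate(genes):
            if g not in keep or totals[i] > totals[keep[g]]:
                keep[g] = i
        order = sorted(keep.values())
        n_dropped = len(genes) - len(order)
        logger.info("collapsed %d duplicate gene rows (kept max-total row)", n_dropped)
        genes = [genes[i] for i in order]
        values = values[order]

    return ExpressionMatrix(genes, cells, values)


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(Path(path), sep="\t", index_label="gene")


def _read_lines(path: Path) -> list[str]:
    if not path.exists():
        raise FileNotFoundError(path)
    out = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


# ---------------------------------------------------------------------------
# cell metadata


def read_cell_metadata(
    path: str | Path, matrix: ExpressionMatrix | None = None
) -> pd.DataFrame:
    """Read per-cell annotations (cluster, sample, phase, response).

    Phase and response tokens are normalized case-insensitively
    ("Responder" -> "R", "Pre-treatment" -> "pre"). When *matrix* is given,
    every matrix cell must be annotated.
    """
    df = pd.read_csv(Path(path), sep="\t", comment="#", dtype=str)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"metadata missing columns: {missing}")
    df = df.loc[:, list(METADATA_COLUMNS)].copy()
    if df["cell_id"].duplicated().any():
        dup = df.loc[df["cell_id"].duplicated(), "cell_id"].iloc[0]
        raise DataError(f"duplicate cell id {dup!r} in metadata")
    df["cluster"] = df["cluster"].astype(int)
    df["phase"] = _normalize(df["phase"], PHASE_TOKENS, "phase")
    df["response"] = _normalize(df["response"], RESPONSE_TOKENS, "response")
    validate_annotation(df)
    if matrix is not None:
        absent = [c for c in matrix.cell_ids if c not in set(df["cell_id"])]
        if absent:
            raise DataError(
                f"{len(absent)} matrix cells missing from metadata, "
                f"first 10: {absent[:10]}"
            )
    return df.reset_index(drop=True)


def validate_annotation(annotation: pd.DataFrame) -> None:
    """Enforce the per-sample consistency invariant of cell annotations."""
    for col in ("phase", "response"):
        per_sample = annotation.groupby("sample_id")[col].nunique()
        bad = per_sample[per_sample > 1]
        if len(bad):
            raise DataError(
                f"samples with mixed {col} labels across their cells: "
                f"{sorted(bad.index)[:10]}"
            )


def write_cell_metadata(annotation: pd.DataFrame, path: str | Path) -> None:
    annotation.loc[:, list(METADATA_COLUMNS)].to_csv(Path(path), sep="\t", index=False)


def _normalize(series: pd.Series, tokens: Mapping[str, str], what: str) -> pd.Series:
    norm = series.str.strip().str.lower()
    unknown = sorted(set(norm) - set(tokens))
    if unknown:
        raise DataError(f"unknown {what} tokens: {unknown}")
    return norm.map(tokens)


# ---------------------------------------------------------------------------
# interaction catalogue (extended SIF)


def read_interactions(path: str | Path) -> PathwayInteractionSet:
    """Read an extended-SIF catalogue: tab-separated source, type, target.

    Extra columns are ignored; self-loops are dropped (count logged) and
    duplicate triples deduplicated.
    """
    records: list[tuple[str, str, str]] = []
    seen: set[tuple[str, str, str]] = set()
    n_self = n_dup = 0
    with open(Path(path), encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataError(f"{path}:{lineno}: expected >=3 fields, got {len(fields)}")
            s, t, o = (fields[0].strip().upper(), fields[1].strip(), fields[2].strip().upper())
            if s == o:
                n_self += 1
                continue
            rec = (s, t, o)
            if rec in seen:
                n_dup += 1
                continue
            seen.add(rec)
            records.append(rec)
    pis = PathwayInteractionSet(records)
    logger.info(
        "read %d interactions (%d self-loops dropped, %d duplicates); %d types: %s",
        len(records), n_self, n_dup, len(pis.types), sorted(pis.types),
    )
    return pis


def write_interactions(interactions: PathwayInteractionSet, path: str | Path) -> None:
    with open(Path(path), "w", encoding="utf-8") as fh:
        for s, t, o in interactions.records:
            fh.write(f"{s}\t{t}\t{o}\n")


# ---------------------------------------------------------------------------
# TF / ligand-receptor annotation sets


def read_annotation_sets(tf_path: str | Path, lr_path: str | Path) -> AnnotationSets:
    """Load the TF list (one symbol per line) and ligand-receptor pair table."""
    tf_lines = _read_lines(Path(tf_path))
    if tf_lines and tf_lines[0].lower() in {"tf", "symbol", "gene"}:
        tf_lines = tf_lines[1:]  # header tolerated
    if not tf_lines:
        raise DataError(f"empty TF file {tf_path}")
    tfs = {t.strip().upper() for t in tf_lines}

    pairs: set[tuple[str, str]] = set()
    with open(Path(lr_path), encoding="utf-8") as fh:
        lines = [
            (i, ln.rstrip("\n"))
            for i, ln in enumerate(fh, 1)
            if ln.strip() and not ln.startswith("#")
        ]
    if lines and lines[0][1].lower().split("\t")[0] in {"ligand", "l"}:
        lines = lines[1:]
    if not lines:
        raise DataError(f"empty ligand-receptor file {lr_path}")
    for lineno, line in lines:
        fields = [f.strip().upper() for f in line.split("\t") if f.strip()]
        if len(fields) < 2:
            raise DataError(f"{lr_path}:{lineno}: expected 2 columns, got {len(fields)}")
        pairs.add((fields[0], fields[1]))
    sets_ = AnnotationSets(tfs=tfs, lr_pairs=pairs)
    logger.info(
        "loaded %d TFs, %d LR pairs (%d ligands, %d receptors)",
        len(tfs), len(pairs), len(sets_.ligands), len(sets_.receptors),
    )
    return sets_


def write_annotation_sets(
    sets_: AnnotationSets, tf_path: str | Path, lr_path: str | Path
) -> None:
    Path(tf_path).write_text("".join(f"{t}\n" for t in sorted(sets_.tfs)))
    Path(lr_path).write_text(
        "".join(f"{l}\t{r}\n" for l, r in sorted(sets_.lr_pairs))
    )


# ---------------------------------------------------------------------------
# bulk cohort


def read_bulk_cohort(expr_path: str | Path, response_path: str | Path) -> BulkCohort:
    """Read a samples x genes bulk expression TSV plus a sample response TSV."""
    df = pd.read_csv(Path(expr_path), sep="\t", comment="#", index_col=0)
    resp = pd.read_csv(Path(response_path), sep="\t", comment="#", dtype=str)
    if not {"sample_id", "response"} <= set(resp.columns):
        raise DataError("response file needs columns sample_id, response")
    resp["response"] = _normalize(resp["response"], RESPONSE_TOKENS, "response")
    lookup = dict(zip(resp["sample_id"], resp["response"]))
    missing = [s for s in df.index if s not in lookup]
    if missing:
        raise DataError(f"samples without response label: {missing[:10]}")
    return BulkCohort(
        sample_ids=[str(s) for s in df.index],
        gene_ids=[str(g).strip().upper() for g in df.columns],
        values=df.to_numpy(dtype=float),
        response=[lookup[str(s)] for s in df.index],
    )


def write_bulk_cohort(
    cohort: BulkCohort, expr_path: str | Path, response_path: str | Path
) -> None:
    pd.DataFrame(
        cohort.values, index=cohort.sample_ids, columns=cohort.gene_ids
    ).to_csv(Path(expr_path), sep="\t", index_label="sample_id")
    with open(Path(response_path), "w", encoding="utf-8") as fh:
        fh.write("sample_id\tresponse\n")
        for s, r in zip(cohort.sample_ids, cohort.response):
            fh.write(f"{s}\t{r}\n")


# ---------------------------------------------------------------------------
# networks (SIF + node attributes)


def write_network(network, sif_path: str | Path, node_attr_path: str | Path) -> None:
    """Write a regulation network as SIF plus a node-attribute TSV.

    The SIF lines are ``source<TAB>type<TAB>target``; edge cluster
    membership goes into a fourth column so the file round-trips exactly.
    """
    edges = sorted(network.edge_clusters)
    with open(Path(sif_path), "w", encoding="utf-8") as fh:
        for e in edges:
            clusters = ",".join(str(c) for c in sorted(network.edge_clusters[e]))
            fh.write(f"{e[0]}\t{e[1]}\t{e[2]}\t{clusters}\n")
    with open(Path(node_attr_path), "w", encoding="utf-8") as fh:
        fh.write("gene\tis_tf\tis_ligand\tis_receptor\tclusters\n")
        for gene in sorted(network.node_clusters):
            tf, lig, rec = network.roles.get(gene, (False, False, False))
            clusters = ",".join(str(c) for c in sorted(network.node_clusters[gene]))
            fh.write(f"{gene}\t{int(tf)}\t{int(lig)}\t{int(rec)}\t{clusters}\n")


def read_network(sif_path: str | Path, node_attr_path: str | Path):
    """Read back a network written by :func:`write_network`."""
    from .networks import RegulationNetwork

    edge_clusters: dict[tuple[str, str, str], set[int]] = {}
    with open(Path(sif_path), encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise DataError(f"{sif_path}:{lineno}: expected >=3 fields")
            clusters = (
                {int(c) for c in fields[3].split(",")} if len(fields) > 3 else set()
            )
            edge_clusters[(fields[0], fields[1], fields[2])] = clusters
    node_clusters: dict[str, set[int]] = {}
    roles: dict[str, tuple[bool, bool, bool]] = {}
    attrs = pd.read_csv(Path(node_attr_path), sep="\t", dtype=str)
    for _, row in attrs.iterrows():
        gene = row["gene"]
        roles[gene] = (
            bool(int(row["is_tf"])),
            bool(int(row["is_ligand"])),
            bool(int(row["is_receptor"])),
        )
        node_clusters[gene] = (
            {int(c) for c in str(row["clusters"]).split(",")}
            if str(row["clusters"]) not in ("", "nan")
            else set()
        )
    return RegulationNetwork(
        edge_clusters=edge_clusters, node_clusters=node_clusters, roles=roles
    )
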