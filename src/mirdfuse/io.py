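"""Readers and writers for association lists, similarity matrices and disease DAGs.

All inputs are plain-text UTF-8: association lists are 2-column TSV/CSV
(disease, miRNA) with ``#`` comments; similarity matrices are square TSV
with a header row and index column; DAG files are 3-column TSV edge lists
(disease_id, child_id, parent_id).  The canonical in-memory encoding of the
association matrix is {0,1} — readers that encounter the -1 convention for
non-association recode it on ingestion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .similarity import DiseaseDAG

logger = logging.getLogger(__name__)

SYMMETRY_TOL = 1e-8
RANGE_TOL = 1e-8


class FormatError(ValueError):
    """Raised when an input file violates the documented layout."""


@dataclass(frozen=True)
class AssociationTable:
    """Deduplicated (disease, miRNA) association records with label orders.

    Label order is first appearance in the source file, which makes every
    downstream matrix deterministic without imposing a sort locale.
    """

    records: tuple[tuple[str, str], ...]
    diseases: tuple[str, ...]
    mirnas: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.records)) != len(self.records):
            raise ValueError("duplicate (disease, miRNA) records")
        if not self.diseases or not self.mirnas:
            raise ValueError("association table needs >=1 disease and >=1 miRNA")


@dataclass
class AssociationMatrix:
    """Binary disease x miRNA adjacency with aligned label lists."""

    Y: np.ndarray
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=float)
        self.row_labels = tuple(self.row_labels)
        self.col_labels = tuple(self.col_labels)
        if self.Y.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("adjacency shape does not match label lengths")
        if len(set(self.row_labels)) != len(self.row_labels):
            raise ValueError("duplicate disease labels")
        if len(set(self.col_labels)) != len(self.col_labels):
            raise ValueError("duplicate miRNA labels")
        if not np.isin(self.Y, (0.0, 1.0)).all():
            raise ValueError("adjacency entries must be 0 or 1")

    @property
    def shape(self) -> tuple[int, int]:
        return self.Y.shape

    def to_records(self) -> list[tuple[str, str]]:
        """Inverse of :func:`build_adjacency` on the positive entries."""
        rows, cols = np.nonzero(self.Y)
        return [(self.row_labels[i], self.col_labels[j]) for i, j in zip(rows, cols)]


@dataclass
class SimilarityMatrix:
    """Symmetric unit-diagonal kernel over diseases or miRNAs."""

    M: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M, dtype=float)
        self.labels = tuple(self.labels)
        n = len(self.labels)
        if self.M.shape != (n, n):
            raise ValueError("similarity matrix shape does not match labels")
        if not np.allclose(self.M, self.M.T, atol=1e-10):
            raise ValueError("similarity matrix must be symmetric")

    @property
    def n(self) -> int:
        return len(self.labels)


def _canon(name: str, casefold: bool) -> str:
    name = name.strip()
    return name.casefold() if casefold else name


def load_associations(
    path: str | Path,
    dialect: str = "disease-mirna",
    casefold: bool = True,
) -> AssociationTable:
    """Parse a 2-column association list into an :class:`AssociationTable`.

    Parameters
    ----------
    path
        TSV or CSV file; ``#`` lines are comments.  Each data line carries at
        least two fields.
    dialect
        ``"disease-mirna"`` (canonical column order) or ``"mirna-disease"``
        (swapped columns, as some exports use).
    casefold
        Case-fold names after whitespace trimming.
    """
    if dialect not in ("disease-mirna", "mirna-disease"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    records: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    n_dup = 0
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split(",")
            if len(fields) < 2:
                raise FormatError(f"{path}: line has fewer than 2 fields: {line!r}")
            a, b = _canon(fields[0], casefold), _canon(fields[1], casefold)
            disease, mirna = (a, b) if dialect == "disease-mirna" else (b, a)
            if not disease or not mirna:
                raise FormatError(f"{path}: empty name in line {line!r}")
            if (disease, mirna) in seen:
                n_dup += 1
                continue
            seen.add((disease, mirna))
            records.append((disease, mirna))
    if not records:
        raise FormatError(f"{path}: no valid association records")
    if n_dup:
        logger.info("dropped %d duplicate association records", n_dup)
    diseases = tuple(dict.fromkeys(d for d, _ in records))
    mirnas = tuple(dict.fromkeys(m for _, m in records))
    return AssociationTable(tuple(records), diseases, mirnas)


def build_adjacency(table: AssociationTable) -> AssociationMatrix:
    """Construct the binary disease x miRNA matrix Y from a record table.

    Y[i, j] = 1 iff (disease_i, mirna_j) is a known association, else 0.
    """
    d_idx = {d: i for i, d in enumerate(table.diseases)}
    m_idx = {m: j for j, m in enumerate(table.mirnas)}
    Y = np.zeros((len(table.diseases), len(table.mirnas)))
    for disease, mirna in table.records:
        Y[d_idx[disease], m_idx[mirna]] = 1.0
    return AssociationMatrix(Y, table.diseases, table.mirnas)


def load_similarity_matrix(
    path: str | Path,
    labels: list[str] | tuple[str, ...] | None = None,
) -> SimilarityMatrix:
    """Load a square TSV similarity matrix, validating kernel properties.

    A header row/index column supplies labels unless ``labels`` overrides
    them (for bare numeric matrices).  Near-symmetric input (max asymmetry
    <= 1e-8) is symmetrized as (M + M^T)/2; anything worse is rejected.  The
    diagonal is forced to 1, logging how many entries were changed.
    """
    path = Path(path)
    if labels is None:
        df = pd.read_csv(path, sep="\t", index_col=0)
        names = tuple(str(c) for c in df.columns)
        if tuple(str(i) for i in df.index) != names:
            raise FormatError(f"{path}: row and column labels disagree")
        M = df.to_numpy(dtype=float)
    else:
        M = np.loadtxt(path, dtype=float, ndmin=2)
        names = tuple(labels)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise FormatError(f"{path}: similarity matrix must be square, got {M.shape}")
    if len(names) != M.shape[0]:
        raise FormatError(f"{path}: {len(names)} labels for {M.shape[0]} rows")
    asym = np.abs(M - M.T).max() if M.size else 0.0
    if asym > SYMMETRY_TOL:
        raise FormatError(f"{path}: asymmetry {asym:g} exceeds tolerance {SYMMETRY_TOL:g}")
    M = (M + M.T) / 2.0
    if M.size and (M.min() < -RANGE_TOL or M.max() > 1.0 + RANGE_TOL):
        raise FormatError(f"{path}: values outside [0, 1] (range [{M.min():g}, {M.max():g}])")
    off_diag = np.abs(np.diag(M) - 1.0) > 1e-12
    if off_diag.any():
        logger.info("forced %d diagonal entries to 1", int(off_diag.sum()))
    np.fill_diagonal(M, 1.0)
    M = np.clip(M, 0.0, 1.0)
    return SimilarityMatrix(M, names)


def save_similarity_matrix(sim: SimilarityMatrix, path: str | Path) -> None:
    pd.DataFrame(sim.M, index=list(sim.labels), columns=list(sim.labels)).to_csv(
        path, sep="\t"
    )


def save_score_matrix(
    F: np.ndarray, row_labels, col_labels, path: str | Path
) -> None:
    """Serialize a real-valued score matrix as labelled TSV."""
    pd.DataFrame(F, index=list(row_labels), columns=list(col_labels)).to_csv(
        path, sep="\t"
    )


def load_score_matrix(path: str | Path) -> tuple[np.ndarray, tuple[str, ...], tuple[str, ...]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return (
        df.to_numpy(dtype=float),
        tuple(str(i) for i in df.index),
        tuple(str(c) for c in df.columns),
    )


def save_associations(mat: AssociationMatrix, path: str | Path) -> None:
    """Write the positive entries of an adjacency matrix as a 2-column TSV."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# disease\tmirna\n")
        for disease, mirna in mat.to_records():
            fh.write(f"{disease}\t{mirna}\n")


def load_dag_edges(path: str | Path) -> dict[str, DiseaseDAG]:
    """Parse a 3-column DAG edge list into per-disease ancestor DAGs.

    Each line is ``disease_id <TAB> child_id <TAB> parent_id``; a line with
    an empty (or missing) parent field declares an isolated node.  Every
    disease must appear in its own DAG, and each per-disease graph must be
    acyclic.
    """
    import networkx as nx

    path = Path(path)
    per_disease: dict[str, tuple[set[str], set[tuple[str, str]]]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = [f.strip() for f in line.split("\t")]
            if len(fields) < 2:
                raise FormatError(f"{path}: DAG line needs >=2 fields: {line!r}")
            disease = fields[0]
            child = fields[1]
            parent = fields[2] if len(fields) > 2 and fields[2] else None
            nodes, edges = per_disease.setdefault(disease, (set(), set()))
            nodes.add(child)
            if parent is not None:
                nodes.add(parent)
                edges.add((child, parent))
    dags: dict[str, DiseaseDAG] = {}
    for disease, (nodes, edges) in per_disease.items():
        if disease not in nodes:
            raise FormatError(f"{path}: disease {disease!r} absent from its own DAG")
        g = nx.DiGraph()
        g.add_nodes_from(nodes)
        g.add_edges_from(edges)
        if not nx.is_directed_acyclic_graph(g):
            raise FormatError(f"{path}: cycle in DAG of disease {disease!r}")
        dags[disease] = DiseaseDAG(frozenset(nodes), frozenset(edges), disease)
    return dags


def save_dag_edges(dags: dict[str, DiseaseDAG], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# disease\tchild\tparent\n")
        for disease, dag in dags.items():
            edges = sorted(dag.edges)
            if not edges:
                fh.write(f"{disease}\t{dag.root}\t\n")
            for child, parent in edges:
                fh.write(f"{disease}\t{child}\t{parent}\n")
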