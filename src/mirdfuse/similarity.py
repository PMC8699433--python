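"""Disease semantic similarity on MeSH-style DAGs and miRNA functional similarity.

Disease terms live in a directed acyclic ancestor graph.  A term contributes
1 to its own semantic value; each ancestor contributes the contribution of
its best descendant within the DAG, decayed by a factor delta per
generation.  The similarity of two diseases is the summed contribution of
their shared terms, normalized by the two semantic values.  miRNA functional
similarity follows the best-match-average (BMA) rule over the disease sets
the two miRNAs are associated with.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

DEFAULT_DELTA = 0.5


@dataclass(frozen=True)
class DiseaseDAG:
    """Ancestor DAG of a single disease term.

    ``edges`` are child -> parent links; ``root`` is the disease term itself
    (the unique node with no incoming child link, at the bottom of the
    ancestor hierarchy).
    """

    nodes: frozenset[str]
    edges: frozenset[tuple[str, str]]
    root: str

    def __post_init__(self) -> None:
        if self.root not in self.nodes:
            raise ValueError(f"root {self.root!r} not among DAG nodes")

    def children_of(self, term: str) -> set[str]:
        """Nodes whose parent link points at ``term`` (within this DAG)."""
        return {c for c, p in self.edges if p == term}


@dataclass(frozen=True)
class SemanticProfile:
    """Per-term semantic contributions and their sum for one disease."""

    contributions: dict[str, float]
    dv: float
    delta: float
    root: str


def semantic_contributions(dag: DiseaseDAG, delta: float = DEFAULT_DELTA) -> SemanticProfile:
    """Compute each term's contribution to the disease's semantic value.

    The disease term itself scores 1; every other term t scores
    ``delta * max(contribution of t's children within the DAG)``, so the
    contribution decays with distance from the disease and multiple paths
    take the maximum, not the sum.
    """
    if not (0.0 < delta < 1.0):
        raise ValueError(f"delta must lie in (0, 1), got {delta}")
    contrib: dict[str, float] = {}

    def score(term: str) -> float:
        if term in contrib:
            return contrib[term]
        if term == dag.root:
            value = 1.0
        else:
            children = dag.children_of(term)
            if not children:
                raise ValueError(
                    f"term {term!r} unreachable from root {dag.root!r}"
                )
            value = delta * max(score(c) for c in children)
        contrib[term] = value
        return value

    for term in dag.nodes:
        score(term)
    return SemanticProfile(contrib, float(sum(contrib.values())), delta, dag.root)


def disease_semantic_similarity(
    profile_i: SemanticProfile, profile_j: SemanticProfile
) -> float:
    """Similarity of two diseases from their shared DAG terms.

    sum over shared terms of (D_i(t) + D_j(t)), divided by DV_i + DV_j.
    Identical DAGs give exactly 1; disjoint term sets give 0.
    """
    if profile_i.delta != profile_j.delta:
        raise ValueError("profiles built with different delta values")
    shared = profile_i.contributions.keys() & profile_j.contributions.keys()
    if not shared:
        return 0.0
    num = sum(profile_i.contributions[t] + profile_j.contributions[t] for t in shared)
    return num / (profile_i.dv + profile_j.dv)


def disease_similarity_matrix(
    dags: dict[str, DiseaseDAG],
    delta: float = DEFAULT_DELTA,
    labels: list[str] | tuple[str, ...] | None = None,
):
    """All-pairs disease semantic similarity as a SimilarityMatrix."""
    from .io import SimilarityMatrix

    names = tuple(labels) if labels is not None else tuple(dags)
    missing = [d for d in names if d not in dags]
    if missing:
        raise KeyError(f"no DAG for diseases: {missing}")
    profiles = [semantic_contributions(dags[d], delta) for d in names]
    n = len(names)
    M = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            M[i, j] = M[j, i] = disease_semantic_similarity(profiles[i], profiles[j])
    return SimilarityMatrix(M, names)


def mirna_functional_similarity(Y, Sd):
    """Best-match-average miRNA functional similarity from associations.

    For miRNAs with associated disease sets D1 and D2,

        sim = [ sum_{d in D1} max_{d' in D2} Sd(d, d')
              + sum_{d in D2} max_{d' in D1} Sd(d, d') ] / (|D1| + |D2|)

    The diagonal is 1.  A miRNA with no associations gets a zero row/column
    (diagonal kept at 1) and triggers a warning.
    """
    from .io import SimilarityMatrix

    Ymat = np.asarray(getattr(Y, "Y", Y), dtype=float)
    S = np.asarray(getattr(Sd, "M", Sd), dtype=float)
    if Ymat.shape[0] != S.shape[0]:
        raise ValueError("association rows must match disease similarity size")
    q = Ymat.shape[1]
    labels = getattr(Y, "col_labels", tuple(f"m{j}" for j in range(q)))
    disease_sets = [np.nonzero(Ymat[:, j])[0] for j in range(q)]
    empty = [j for j in range(q) if disease_sets[j].size == 0]
    if empty:
        warnings.warn(
            f"{len(empty)} miRNA(s) have no associations; their similarity is 0",
            stacklevel=2,
        )
    M = np.zeros((q, q))
    for j in range(q):
        Dj = disease_sets[j]
        if Dj.size == 0:
            continue
        for k in range(j + 1, q):
            Dk = disease_sets[k]
            if Dk.size == 0:
                continue
            block = S[np.ix_(Dj, Dk)]
            M[j, k] = M[k, j] = (
                block.max(axis=1).sum() + block.max(axis=0).sum()
            ) / (Dj.size + Dk.size)
    np.fill_diagonal(M, 1.0)
    return SimilarityMatrix(M, tuple(labels))
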