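"""Synthetic desk-scale datasets with the structure the method assumes.

The generator plants a low-rank latent structure shared by the association
matrix and both similarity kernels: latent factors G_d (diseases) and G_m
(miRNAs) produce true link scores sigma(G_d G_m^T), the binary matrix Y is
the top `density` fraction of those scores (optionally label-flipped), and
the kernels are row-cosine similarities of the latent factors (optionally
noised).  Because all three submodels assume similarity is informative
about associations, the kernels are built from the same factors that
generate Y; `sim_noise` dials that informativeness down.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .io import AssociationMatrix, SimilarityMatrix
from .similarity import DiseaseDAG


@dataclass
class SyntheticSpec:
    """Study conditions of a synthetic dataset.

    p x q matrix with a planted latent dimension `rank`; `density` is the
    fraction of pairs labelled positive; `flip_noise` flips that fraction of
    entries after thresholding; `sim_noise` is the s.d. of Gaussian noise
    added to the similarity kernels.
    """

    p: int = 60
    q: int = 60
    rank: int = 4
    density: float = 0.1
    sim_noise: float = 0.0
    flip_noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.density < 1):
            raise ValueError("density must lie in (0, 1)")
        if self.rank > min(self.p, self.q):
            raise ValueError("rank must not exceed min(p, q)")
        if not (0 <= self.flip_noise < 0.5):
            raise ValueError("flip_noise must lie in [0, 0.5)")
        if self.sim_noise < 0:
            raise ValueError("sim_noise must be >= 0")


def _cosine_kernel(G: np.ndarray, noise: float, rng: np.random.Generator) -> np.ndarray:
    norms = np.linalg.norm(G, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    X = G / norms
    S = X @ X.T
    if noise > 0:
        E = rng.normal(scale=noise, size=S.shape)
        S = S + (E + E.T) / 2.0
    S = (S + S.T) / 2.0
    S = np.clip(S, 0.0, 1.0)
    np.fill_diagonal(S, 1.0)
    return S


def generate_dataset(spec: SyntheticSpec):
    """Draw one synthetic dataset; bit-identical outputs per seed.

    Returns (AssociationMatrix, disease SimilarityMatrix, miRNA
    SimilarityMatrix, true score matrix).
    """
    rng = np.random.default_rng(spec.seed)
    G_d = rng.normal(size=(spec.p, spec.rank))
    G_m = rng.normal(size=(spec.q, spec.rank))
    truth = expit(G_d @ G_m.T)
    n_pos = int(round(spec.density * spec.p * spec.q))
    flat = np.argsort(truth, axis=None)[::-1][:n_pos]
    Y = np.zeros(spec.p * spec.q)
    Y[flat] = 1.0
    Y = Y.reshape(spec.p, spec.q)
    if spec.flip_noise > 0:
        n_flip = int(round(spec.flip_noise * spec.p * spec.q))
        idx = rng.choice(spec.p * spec.q, size=n_flip, replace=False)
        Yf = Y.ravel()
        Yf[idx] = 1.0 - Yf[idx]
        Y = Yf.reshape(spec.p, spec.q)
    d_labels = tuple(f"disease_{i:03d}" for i in range(spec.p))
    m_labels = tuple(f"mir-{j:03d}" for j in range(spec.q))
    Sd = _cosine_kernel(G_d, spec.sim_noise, rng)
    Sm = _cosine_kernel(G_m, spec.sim_noise, rng)
    return (
        AssociationMatrix(Y, d_labels, m_labels),
        SimilarityMatrix(Sd, d_labels),
        SimilarityMatrix(Sm, m_labels),
        truth,
    )


def generate_toy_dags(topology: str, depth: int = 3) -> dict[str, DiseaseDAG]:
    """Small named DAG fixtures: ``chain``, ``diamond`` or ``disjoint``.

    chain: a single disease whose ancestors form a path of `depth` nodes.
    diamond: 4 nodes, two parallel paths from the disease to one ancestor.
    disjoint: two chain diseases sharing no term ids.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if topology == "chain":
        nodes = ["d_chain"] + [f"t{i}" for i in range(1, depth)]
        edges = {(nodes[i], nodes[i + 1]) for i in range(depth - 1)}
        return {"d_chain": DiseaseDAG(frozenset(nodes), frozenset(edges), "d_chain")}
    if topology == "diamond":
        nodes = ["d_diamond", "left", "right", "top"]
        edges = {
            ("d_diamond", "left"),
            ("d_diamond", "right"),
            ("left", "top"),
            ("right", "top"),
        }
        return {"d_diamond": DiseaseDAG(frozenset(nodes), frozenset(edges), "d_diamond")}
    if topology == "disjoint":
        out = {}
        for tag in ("x", "y"):
            nodes = [f"d_{tag}"] + [f"{tag}{i}" for i in range(1, depth)]
            edges = {(nodes[i], nodes[i + 1]) for i in range(depth - 1)}
            out[f"d_{tag}"] = DiseaseDAG(frozenset(nodes), frozenset(edges), f"d_{tag}")
        return out
    raise ValueError(f"unknown topology {topology!r}")
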