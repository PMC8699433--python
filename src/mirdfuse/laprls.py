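"""Laplacian regularized least squares (LapRLS) submodel.

Kernel regression on each side of the bipartite association matrix with a
normalized graph-Laplacian smoothness penalty.  Each side has the closed
form F* = W (W + beta L W + eps I)^{-1} Y; the disease-side and miRNA-side
solutions are averaged elementwise, F* = (Fd* + Fm*^T) / 2.  The kernels
are the disease semantic similarity and miRNA functional similarity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class LaprlsParams:
    """beta_d / beta_m weight the Laplacian penalty on each side;
    ridge_eps is a small jitter guaranteeing invertibility."""

    beta_d: float = 0.3
    beta_m: float = 0.3
    ridge_eps: float = 1e-6

    def __post_init__(self) -> None:
        if self.beta_d < 0 or self.beta_m < 0:
            raise ValueError("beta_d and beta_m must be >= 0")
        if not (0 <= self.ridge_eps <= 1e-4):
            raise ValueError("ridge_eps must lie in [0, 1e-4]")


@dataclass
class KernelPair:
    """Side kernels and their normalized Laplacians, aligned to Y's labels."""

    Wd: np.ndarray
    Wm: np.ndarray
    Ld: np.ndarray
    Lm: np.ndarray

    @classmethod
    def from_similarities(cls, disease_sim, mirna_sim) -> "KernelPair":
        Wd = np.asarray(getattr(disease_sim, "M", disease_sim), dtype=float)
        Wm = np.asarray(getattr(mirna_sim, "M", mirna_sim), dtype=float)
        return cls(Wd, Wm, normalized_laplacian(Wd), normalized_laplacian(Wm))


def normalized_laplacian(W) -> np.ndarray:
    """Symmetric normalized Laplacian L = I - D^{-1/2} W D^{-1/2}.

    D is the diagonal of row sums; eigenvalues lie in [0, 2].  A node with
    zero row sum keeps a zeroed off-diagonal and a unit diagonal.
    """
    W = np.asarray(getattr(W, "M", W), dtype=float)
    if not np.allclose(W, W.T, atol=1e-10):
        raise ValueError("kernel must be symmetric")
    if W.size and W.min() < 0:
        raise ValueError("kernel must be nonnegative")
    d = W.sum(axis=1)
    zero = d <= 0
    if zero.any():
        logger.warning("%d nodes have zero degree; isolated in the Laplacian", zero.sum())
    inv_root = np.zeros_like(d)
    inv_root[~zero] = 1.0 / np.sqrt(d[~zero])
    L = np.eye(W.shape[0]) - (inv_root[:, None] * W * inv_root[None, :])
    return (L + L.T) / 2.0


def laprls_solve(
    Y_side: np.ndarray,
    W: np.ndarray,
    L: np.ndarray,
    beta: float,
    ridge_eps: float = 1e-6,
) -> np.ndarray:
    """Closed-form one-sided solution F* = W (W + beta L W + eps I)^{-1} Y.

    With beta = 0, eps = 0 and invertible W this returns Y_side exactly.
    """
    W = np.asarray(W, dtype=float)
    n = W.shape[0]
    lhs = W + beta * (L @ W) + ridge_eps * np.eye(n)
    try:
        alpha = np.linalg.solve(lhs, Y_side)
    except np.linalg.LinAlgError as err:
        cond = np.linalg.cond(lhs)
        raise np.linalg.LinAlgError(
            f"one-sided system singular even after ridge jitter "
            f"(condition number {cond:.3g})"
        ) from err
    return W @ alpha


def laprls_predict(Y, kernels: KernelPair, params: LaprlsParams) -> np.ndarray:
    """Two-sided LapRLS prediction F* = (Fd* + Fm*^T) / 2.

    Fd* solves the disease-side problem on Y (p x q); Fm* solves the
    miRNA-side problem on Y^T.
    """
    Ymat = np.asarray(getattr(Y, "Y", Y), dtype=float)
    Fd = laprls_solve(Ymat, kernels.Wd, kernels.Ld, params.beta_d, params.ridge_eps)
    Fm = laprls_solve(Ymat.T, kernels.Wm, kernels.Lm, params.beta_m, params.ridge_eps)
    return (Fd + Fm.T) / 2.0


class LapRLS:
    """Laplacian regularized least squares model over a disease x miRNA matrix."""

    def __init__(self, Y, mirna_sim, disease_sim, params: LaprlsParams | None = None):
        self.Y = np.asarray(getattr(Y, "Y", Y), dtype=float)
        self.params = params or LaprlsParams()
        self.kernels = KernelPair.from_similarities(disease_sim, mirna_sim)

    def fit(self) -> "LapRLSResults":
        scores = laprls_predict(self.Y, self.kernels, self.params)
        return LapRLSResults(self, scores)


@dataclass
class LapRLSResults:
    model: LapRLS
    scores: np.ndarray

    def predict(self) -> np.ndarray:
        return self.scores

    def summary(self) -> str:
        p, q = self.scores.shape
        return (
            f"LapRLS fit: {p} diseases x {q} miRNAs\n"
            f"  beta_d={self.model.params.beta_d}, beta_m={self.model.params.beta_m}"
        )
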