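"""Neighborhood-regularized logistic matrix factorization (NRLMF) submodel.

Models the probability of a disease-miRNA link as a logistic function of a
latent inner product, P_ij = sigma(u_i v_j^T), with observed positives
up-weighted by a factor c and the latent vectors smoothed over k-NN graph
Laplacians built from the two similarity kernels.  Optimized with full-batch
AdaGrad on the analytic gradients.

Orientation: rows (U, index i, size m) are diseases; columns (V, index j,
size n) are miRNAs, so the predicted P is disease x miRNA like Y.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, log1p

logger = logging.getLogger(__name__)


@dataclass
class NrlmfParams:
    """NRLMF hyperparameters.

    c >= 1 is the importance weight on observed positives; lambda_d/lambda_t
    are Tikhonov weights on the disease/miRNA factors; alpha/beta weight the
    respective graph-Laplacian smoothing; k_nn is the neighborhood size of
    the sparsified similarity graphs.
    """

    rank: int = 50
    c: float = 5.0
    lambda_d: float = 0.625
    lambda_t: float = 0.625
    alpha: float = 0.1
    beta: float = 0.1
    k_nn: int = 5
    learn_rate: float = 0.1
    max_iter: int = 100
    seed: int = 0
    smooth_new_entities: bool = False

    def __post_init__(self) -> None:
        if self.c < 1:
            raise ValueError("c must be >= 1")
        if self.lambda_d <= 0 or self.lambda_t <= 0:
            raise ValueError("lambda_d and lambda_t must be > 0")
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be >= 0")


@dataclass
class NeighborhoodLaplacian:
    """Unnormalized Laplacian L = D - W of a symmetrized k-NN similarity graph."""

    L: np.ndarray
    W_knn: np.ndarray


@dataclass
class LogisticFactors:
    """Latent factors and the implied link-probability matrix."""

    U: np.ndarray
    V: np.ndarray

    @property
    def P(self) -> np.ndarray:
        return expit(self.U @ self.V.T)


def build_knn_laplacian(S, k_nn: int) -> NeighborhoodLaplacian:
    """Sparsify a similarity kernel to its k-NN graph and take L = D - W.

    Each row keeps its k_nn largest off-diagonal similarities; the result is
    symmetrized as (W + W^T)/2.  L is positive semidefinite by construction.
    """
    S = np.asarray(getattr(S, "M", S), dtype=float)
    n = S.shape[0]
    if not (1 <= k_nn < n):
        raise ValueError(f"k_nn must lie in [1, {n - 1}], got {k_nn}")
    off = S.copy()
    np.fill_diagonal(off, -np.inf)
    W = np.zeros_like(S)
    for i in range(n):
        keep = np.argpartition(off[i], -k_nn)[-k_nn:]
        W[i, keep] = S[i, keep]
    W = (W + W.T) / 2.0
    L = np.diag(W.sum(axis=1)) - W
    return NeighborhoodLaplacian(L, W)


def _softplus(X: np.ndarray) -> np.ndarray:
    # log(1 + exp(x)) without overflow for large |x|
    return np.maximum(X, 0.0) + log1p(np.exp(-np.abs(X)))


def nrlmf_objective(
    U: np.ndarray,
    V: np.ndarray,
    Y: np.ndarray,
    Ld: np.ndarray,
    Lt: np.ndarray,
    params: NrlmfParams,
) -> float:
    """Weighted logistic loss plus Tikhonov and Laplacian quadratic forms.

    sum_ij (1 + c y_ij - y_ij) log(1 + exp(u_i v_j^T)) - c y_ij u_i v_j^T
      + 1/2 tr[U^T (lambda_d I + alpha Ld) U]
      + 1/2 tr[V^T (lambda_t I + beta Lt) V]
    """
    X = U @ V.T
    c = params.c
    loss = float(np.sum((1.0 + (c - 1.0) * Y) * _softplus(X)) - c * np.sum(Y * X))
    Rd = params.lambda_d * np.eye(U.shape[0]) + params.alpha * Ld
    Rt = params.lambda_t * np.eye(V.shape[0]) + params.beta * Lt
    loss += 0.5 * float(np.trace(U.T @ Rd @ U)) + 0.5 * float(np.trace(V.T @ Rt @ V))
    return loss


def nrlmf_gradients(
    U: np.ndarray,
    V: np.ndarray,
    Y: np.ndarray,
    Ld: np.ndarray,
    Lt: np.ndarray,
    params: NrlmfParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Analytic gradients of the NRLMF objective.

    dL/dU = P V + (c-1)(Y o P) V - c Y V + (lambda_d I + alpha Ld) U
    dL/dV = P^T U + (c-1)(Y^T o P^T) U - c Y^T U + (lambda_t I + beta Lt) V
    where P = sigma(U V^T) and o is the Hadamard product.
    """
    c = params.c
    P = expit(U @ V.T)
    grad_u = P @ V + (c - 1.0) * ((Y * P) @ V) - c * (Y @ V)
    grad_u += params.lambda_d * U + params.alpha * (Ld @ U)
    grad_v = P.T @ U + (c - 1.0) * ((Y * P).T @ U) - c * (Y.T @ U)
    grad_v += params.lambda_t * V + params.beta * (Lt @ V)
    return grad_u, grad_v


def fit_nrlmf(
    Y: np.ndarray,
    disease_sim,
    mirna_sim,
    params: NrlmfParams,
) -> tuple[LogisticFactors, list[float]]:
    """AdaGrad descent on the NRLMF objective from a seeded Gaussian init.

    Y is p x q disease x miRNA with entries in {0,1}.  Returns the iterate
    with the lowest objective seen, plus the objective trace.
    """
    Y = np.asarray(Y, dtype=float)
    m, n = Y.shape
    Sd = np.asarray(getattr(disease_sim, "M", disease_sim), dtype=float)
    Sm = np.asarray(getattr(mirna_sim, "M", mirna_sim), dtype=float)
    Ld = build_knn_laplacian(Sd, params.k_nn).L
    Lt = build_knn_laplacian(Sm, params.k_nn).L
    rng = np.random.default_rng(params.seed)
    r = params.rank
    U = rng.normal(scale=1.0 / np.sqrt(r), size=(m, r))
    V = rng.normal(scale=1.0 / np.sqrt(r), size=(n, r))
    gsq_u = np.zeros_like(U)
    gsq_v = np.zeros_like(V)
    trace = [nrlmf_objective(U, V, Y, Ld, Lt, params)]
    best = (trace[0], U.copy(), V.copy())
    for _ in range(params.max_iter):
        gu, gv = nrlmf_gradients(U, V, Y, Ld, Lt, params)
        gsq_u += gu**2
        gsq_v += gv**2
        U = U - params.learn_rate * gu / np.sqrt(gsq_u + 1e-10)
        V = V - params.learn_rate * gv / np.sqrt(gsq_v + 1e-10)
        obj = nrlmf_objective(U, V, Y, Ld, Lt, params)
        if not np.isfinite(obj):
            raise FloatingPointError(
                f"NRLMF objective became non-finite at iteration {len(trace)}; "
                f"last finite value {trace[-1]:.6g}"
            )
        trace.append(obj)
        if obj < best[0]:
            best = (obj, U.copy(), V.copy())
    factors = LogisticFactors(best[1], best[2])
    if params.smooth_new_entities:
        factors = _smooth_cold_entities(factors, Y, Sd, Sm, params.k_nn)
    return factors, trace


def _smooth_cold_entities(
    factors: LogisticFactors, Y: np.ndarray, Sd: np.ndarray, Sm: np.ndarray, k_nn: int
) -> LogisticFactors:
    """Replace factors of entities without training positives by the
    similarity-weighted mean of their k nearest neighbors' factors."""
    U, V = factors.U.copy(), factors.V.copy()
    for X, S, axis in ((U, Sd, 1), (V, Sm, 0)):
        counts = Y.sum(axis=axis)
        for i in np.nonzero(counts == 0)[0]:
            sims = S[i].copy()
            sims[i] = -np.inf
            nbrs = np.argpartition(sims, -k_nn)[-k_nn:]
            w = np.clip(S[i, nbrs], 0.0, None)
            if w.sum() > 0:
                X[i] = (w[:, None] * X[nbrs]).sum(axis=0) / w.sum()
    return LogisticFactors(U, V)


def predict_nrlmf(factors: LogisticFactors) -> np.ndarray:
    """Predicted link probabilities P = sigma(U V^T), entries in (0, 1)."""
    return factors.P


class NRLMF:
    """Neighborhood-regularized logistic matrix factorization model."""

    def __init__(self, Y, mirna_sim, disease_sim, params: NrlmfParams | None = None):
        self.Y = np.asarray(getattr(Y, "Y", Y), dtype=float)
        self.Sm = np.asarray(getattr(mirna_sim, "M", mirna_sim), dtype=float)
        self.Sd = np.asarray(getattr(disease_sim, "M", disease_sim), dtype=float)
        self.params = params or NrlmfParams()

    def fit(self) -> "NRLMFResults":
        factors, trace = fit_nrlmf(self.Y, self.Sd, self.Sm, self.params)
        return NRLMFResults(self, factors, trace)


@dataclass
class NRLMFResults:
    model: NRLMF
    factors: LogisticFactors
    objective_trace: list[float] = field(repr=False)

    @property
    def objective(self) -> float:
        return min(self.objective_trace)

    def predict(self) -> np.ndarray:
        return predict_nrlmf(self.factors)

    def summary(self) -> str:
        m, r = self.factors.U.shape
        n = self.factors.V.shape[0]
        return (
            f"NRLMF fit: {m} diseases x {n} miRNAs, rank {r}\n"
            f"  iterations: {len(self.objective_trace) - 1}\n"
            f"  objective: {self.objective_trace[0]:.6g} -> {self.objective:.6g}"
        )
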