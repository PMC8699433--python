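"""Collaborative matrix factorization (CMF) submodel.

Factors the miRNA x disease association matrix as Y ~ A B^T while pushing
the latent factors to reproduce the similarity kernels, Sm ~ A A^T and
Sd ~ B B^T.  Fitting is alternating least squares with closed-form ridge
block updates; each accepted update is damped until the objective is
non-increasing, so the objective trace is monotone.

Orientation: the block-update algebra works on the q x p (miRNA x disease)
matrix so that Y ~ A B^T with A holding miRNA features.  The Model class
accepts the pipeline's p x q disease x miRNA matrix and transposes on entry;
predictions come back in disease x miRNA orientation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class CmfParams:
    """Tuning knobs of the CMF objective and its ALS solver.

    rank is the latent dimension; lambda_l the Tikhonov weight on both
    factors; lambda_m / lambda_d weight the similarity-consistency penalties
    on the miRNA / disease side.
    """

    rank: int = 50
    lambda_l: float = 0.5
    lambda_m: float = 0.125
    lambda_d: float = 0.125
    max_iter: int = 100
    tol: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rank < 1:
            raise ValueError("rank must be positive")
        if min(self.lambda_l, self.lambda_m, self.lambda_d) < 0:
            raise ValueError("regularization weights must be >= 0")


@dataclass
class LatentFactors:
    """A: q x k miRNA features; B: p x k disease features."""

    A: np.ndarray
    B: np.ndarray

    def __post_init__(self) -> None:
        if not (np.isfinite(self.A).all() and np.isfinite(self.B).all()):
            raise ValueError("latent factors must be finite")
        if self.A.shape[1] != self.B.shape[1]:
            raise ValueError("factor ranks disagree")


def cmf_objective(
    A: np.ndarray,
    B: np.ndarray,
    Y: np.ndarray,
    Sm: np.ndarray,
    Sd: np.ndarray,
    params: CmfParams,
) -> float:
    """Frobenius objective: reconstruction + ridge + similarity consistency.

    ||Y - AB^T||_F^2 + lambda_l (||A||_F^2 + ||B||_F^2)
      + lambda_m ||Sm - AA^T||_F^2 + lambda_d ||Sd - BB^T||_F^2
    with Y in q x p (miRNA x disease) orientation.
    """
    if Y.shape != (A.shape[0], B.shape[0]):
        raise ValueError(f"shape mismatch: Y {Y.shape}, A {A.shape}, B {B.shape}")
    obj = float(np.sum((Y - A @ B.T) ** 2))
    obj += params.lambda_l * float(np.sum(A**2) + np.sum(B**2))
    if params.lambda_m:
        obj += params.lambda_m * float(np.sum((Sm - A @ A.T) ** 2))
    if params.lambda_d:
        obj += params.lambda_d * float(np.sum((Sd - B @ B.T) ** 2))
    return obj


def _svd_init(Y: np.ndarray, rank: int) -> tuple[np.ndarray, np.ndarray]:
    U, s, Vt = np.linalg.svd(Y, full_matrices=False)
    k = min(rank, s.size)
    root = np.sqrt(s[:k])
    A = U[:, :k] * root
    B = Vt[:k].T * root
    if k < rank:  # pad with zero columns to the requested rank
        A = np.hstack([A, np.zeros((A.shape[0], rank - k))])
        B = np.hstack([B, np.zeros((B.shape[0], rank - k))])
    return A, B


def _ridge_solve(rhs: np.ndarray, gram: np.ndarray, lam: float) -> np.ndarray:
    """Solve X @ (gram + lam I) = rhs for X, jittering if singular."""
    k = gram.shape[0]
    lhs = gram + lam * np.eye(k)
    try:
        return np.linalg.solve(lhs.T, rhs.T).T
    except np.linalg.LinAlgError:
        logger.warning("singular normal equations; adding ridge jitter 1e-8")
        return np.linalg.solve((lhs + 1e-8 * np.eye(k)).T, rhs.T).T


def _damped_accept(update, current, objective, max_halvings: int = 40):
    """Halve the step toward ``update`` until the objective does not increase."""
    obj_cur = objective(current)
    cand = update
    for _ in range(max_halvings):
        if objective(cand) <= obj_cur:
            return cand
        cand = (cand + current) / 2.0
    return current


def fit_cmf(
    Y: np.ndarray,
    Sm: np.ndarray,
    Sd: np.ndarray,
    params: CmfParams,
) -> tuple[LatentFactors, list[float]]:
    """Alternating least squares for the CMF objective.

    Y is q x p (miRNA x disease).  Initialization is the truncated SVD of Y,
    so the fit is deterministic; the seed only matters for the random
    fallback used when Y is identically zero.  Returns the factors and the
    monotone objective trace (initial value first).
    """
    Y = np.asarray(Y, dtype=float)
    q, p = Y.shape
    if params.rank > min(p, q):
        raise ValueError(f"rank {params.rank} exceeds min(p, q) = {min(p, q)}")
    if np.any(Y):
        A, B = _svd_init(Y, params.rank)
    else:
        rng = np.random.default_rng(params.seed)
        A = rng.normal(scale=0.01, size=(q, params.rank))
        B = rng.normal(scale=0.01, size=(p, params.rank))
    lam_l, lam_m, lam_d = params.lambda_l, params.lambda_m, params.lambda_d
    trace = [cmf_objective(A, B, Y, Sm, Sd, params)]
    for _ in range(params.max_iter):
        # miRNA-side block: A (B^T B + lam I + 2 lam_m A^T A) = Y B + 2 lam_m Sm A
        rhs = Y @ B + 2.0 * lam_m * (Sm @ A)
        gram = B.T @ B + 2.0 * lam_m * (A.T @ A)
        A_new = _ridge_solve(rhs, gram, lam_l)
        A = _damped_accept(A_new, A, lambda X: cmf_objective(X, B, Y, Sm, Sd, params))
        # disease-side block, symmetric role
        rhs = Y.T @ A + 2.0 * lam_d * (Sd @ B)
        gram = A.T @ A + 2.0 * lam_d * (B.T @ B)
        B_new = _ridge_solve(rhs, gram, lam_l)
        B = _damped_accept(B_new, B, lambda X: cmf_objective(A, X, Y, Sm, Sd, params))
        trace.append(cmf_objective(A, B, Y, Sm, Sd, params))
        if abs(trace[-2] - trace[-1]) <= params.tol * max(abs(trace[-2]), 1e-12):
            break
    return LatentFactors(A, B), trace


def predict_cmf(factors: LatentFactors) -> np.ndarray:
    """Score matrix F = (A B^T)^T = B A^T in disease x miRNA orientation."""
    return factors.B @ factors.A.T


class CMF:
    """Collaborative matrix factorization model over a disease x miRNA matrix.

    Parameters
    ----------
    Y : (p, q) array
        Binary disease x miRNA associations.
    mirna_sim : (q, q) array
        miRNA functional similarity kernel.
    disease_sim : (p, p) array
        Disease semantic similarity kernel.
    params : CmfParams
    """

    def __init__(self, Y, mirna_sim, disease_sim, params: CmfParams | None = None):
        self.Y = np.asarray(getattr(Y, "Y", Y), dtype=float)
        self.Sm = np.asarray(getattr(mirna_sim, "M", mirna_sim), dtype=float)
        self.Sd = np.asarray(getattr(disease_sim, "M", disease_sim), dtype=float)
        self.params = params or CmfParams()

    def fit(self) -> "CMFResults":
        factors, trace = fit_cmf(self.Y.T, self.Sm, self.Sd, self.params)
        return CMFResults(self, factors, trace)


@dataclass
class CMFResults:
    model: CMF
    factors: LatentFactors
    objective_trace: list[float] = field(repr=False)

    @property
    def objective(self) -> float:
        return self.objective_trace[-1]

    def predict(self) -> np.ndarray:
        """Disease x miRNA score matrix F = B A^T."""
        return predict_cmf(self.factors)

    def summary(self) -> str:
        p, k = self.factors.B.shape
        q = self.factors.A.shape[0]
        return (
            f"CMF fit: {p} diseases x {q} miRNAs, rank {k}\n"
            f"  iterations: {len(self.objective_trace) - 1}\n"
            f"  objective: {self.objective_trace[0]:.6g} -> {self.objective:.6g}"
        )
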