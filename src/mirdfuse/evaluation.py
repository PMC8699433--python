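"""Cross-validation folds, ranking metrics, method comparison, candidate ranking.

The cross-validation unit is the known association (pair-level masking):
positives are shuffled and partitioned into k test sets; the remaining
positives of each fold are split 8:1 into submodel-training and
weight-validation sets.  Reported AUC/AUPR use all unknown pairs as
negatives (deterministic given folds); negative sampling happens only
inside the Q-learning loop.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

logger = logging.getLogger(__name__)

METHODS = ("CMF", "NRLMF", "LapRLS", "Mean-Weighted", "Q-Fusion")


@dataclass(frozen=True)
class FoldSpec:
    """Disjoint train/validation/test positive index sets of one CV fold."""

    fold_id: int
    train_pos: np.ndarray  # (n, 2) arrays of (row, col) indices
    val_pos: np.ndarray
    test_pos: np.ndarray
    seed: int


@dataclass(frozen=True)
class EvalResult:
    auc: float
    aupr: float
    n_pos: int
    n_neg: int


def make_folds(Y, k: int = 5, seed: int = 0) -> list[FoldSpec]:
    """Partition the known associations into k folds with an 8:1 train:val
    split of each fold's non-test positives.  Deterministic per seed."""
    Ymat = np.asarray(getattr(Y, "Y", Y), dtype=float)
    if k < 2:
        raise ValueError("k must be >= 2")
    positives = np.argwhere(Ymat == 1)
    if len(positives) < k:
        raise ValueError(f"need >= {k} positives for {k}-fold CV, have {len(positives)}")
    rng = np.random.default_rng(seed)
    positives = positives[rng.permutation(len(positives))]
    chunks = np.array_split(positives, k)
    folds = []
    for f in range(k):
        test = chunks[f]
        rest = np.concatenate([chunks[g] for g in range(k) if g != f])
        n_val = max(1, round(len(rest) / 9))
        folds.append(
            FoldSpec(f, train_pos=rest[n_val:], val_pos=rest[:n_val], test_pos=test, seed=seed)
        )
    return folds


def auc_score(scores, labels) -> float:
    """Area under the ROC curve (Mann-Whitney statistic, ties half-credit)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC requires both classes present")
    return float(roc_auc_score(labels, scores))


def aupr_score(scores, labels) -> float:
    """Step-wise (non-interpolated) area under the precision-recall curve."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if labels.sum() < 1:
        raise ValueError("AUPR requires at least one positive")
    return float(average_precision_score(labels, scores))


def rank_candidates(
    F: np.ndarray,
    row_labels,
    col_labels,
    disease: str,
    known_pos: set[str] | None = None,
    top_k: int = 50,
) -> pd.DataFrame:
    """Rank a disease's candidate miRNAs by score, excluding known positives.

    Ties are broken by miRNA label (lexicographic) so the listing is
    deterministic.  Returns a DataFrame with columns rank, mirna, score.
    """
    row_labels = list(row_labels)
    col_labels = list(col_labels)
    if disease not in row_labels:
        raise KeyError(f"unknown disease {disease!r}")
    known_pos = known_pos or set()
    i = row_labels.index(disease)
    entries = [
        (col_labels[j], float(F[i, j]))
        for j in range(len(col_labels))
        if col_labels[j] not in known_pos
    ]
    entries.sort(key=lambda e: (-e[1], e[0]))
    entries = entries[:top_k]
    return pd.DataFrame(
        {
            "rank": np.arange(1, len(entries) + 1),
            "mirna": [e[0] for e in entries],
            "score": [e[1] for e in entries],
        }
    )


def _masked_matrix(shape, positives) -> np.ndarray:
    Y = np.zeros(shape)
    if len(positives):
        Y[positives[:, 0], positives[:, 1]] = 1.0
    return Y


def sample_negatives(Ymat: np.ndarray, n: int, seed: int) -> np.ndarray:
    """Sample n unknown pairs uniformly without replacement (seeded)."""
    unknown = np.argwhere(Ymat == 0)
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(unknown), size=min(n, len(unknown)), replace=False)
    return unknown[idx]


def fit_submodels(Y_train, mirna_sim, disease_sim, config):
    """Fit CMF, NRLMF and LapRLS on a training matrix; return min-max
    normalized score matrices in a fixed (F1, F2, F3) = (CMF, NRLMF, LapRLS)
    order."""
    from .cmf import CMF
    from .fusion import minmax_normalize
    from .laprls import LapRLS
    from .nrlmf import NRLMF

    f1 = CMF(Y_train, mirna_sim, disease_sim, config.cmf).fit().predict()
    f2 = NRLMF(Y_train, mirna_sim, disease_sim, config.nrlmf).fit().predict()
    f3 = LapRLS(Y_train, mirna_sim, disease_sim, config.laprls).fit().predict()
    return tuple(minmax_normalize(f) for f in (f1, f2, f3))


def evaluate_pipeline(dataset, config) -> pd.DataFrame:
    """Compare the three submodels, equal-weight fusion, and Q-learned fusion
    under a shared k-fold protocol.

    Parameters
    ----------
    dataset
        Tuple (Y, disease_sim, mirna_sim) of an association matrix and the
        two similarity kernels (wrappers or arrays).
    config : PipelineConfig

    Returns
    -------
    DataFrame indexed by method with columns auc and aupr (means over folds
    by default; ``config.auc_mode="pooled"`` pools scores across folds).
    """
    from dataclasses import replace

    from .fusion import WeightState, fuse, train_fusion

    Y, disease_sim, mirna_sim = dataset
    Ymat = np.asarray(getattr(Y, "Y", Y), dtype=float)
    folds = make_folds(Ymat, config.folds, config.seed)
    mean_state = WeightState.initial(config.qlearn.h)
    per_fold: dict[str, list[EvalResult]] = {m: [] for m in METHODS}
    pooled: dict[str, list[tuple[np.ndarray, np.ndarray]]] = {m: [] for m in METHODS}
    learned_weights = []
    for fold in folds:
        Y_train = _masked_matrix(Ymat.shape, fold.train_pos)
        F1, F2, F3 = fit_submodels(Y_train, mirna_sim, disease_sim, config)
        val_neg = sample_negatives(
            Ymat, len(fold.val_pos), seed=config.seed * 1000 + fold.fold_id
        )
        qparams = replace(config.qlearn, seed=config.qlearn.seed + fold.fold_id)
        state, _, _ = train_fusion(
            F1, F2, F3, fold.val_pos, val_neg, qparams, normalize=False
        )
        learned_weights.append(state.weights)
        scored = {
            "CMF": F1,
            "NRLMF": F2,
            "LapRLS": F3,
            "Mean-Weighted": fuse(F1, F2, F3, mean_state),
            "Q-Fusion": fuse(F1, F2, F3, state),
        }
        neg_mask = Ymat == 0
        test_rows, test_cols = fold.test_pos[:, 0], fold.test_pos[:, 1]
        for method, F in scored.items():
            scores = np.concatenate([F[test_rows, test_cols], F[neg_mask]])
            labels = np.concatenate(
                [np.ones(len(fold.test_pos)), np.zeros(int(neg_mask.sum()))]
            )
            per_fold[method].append(
                EvalResult(
                    auc_score(scores, labels),
                    aupr_score(scores, labels),
                    len(fold.test_pos),
                    int(neg_mask.sum()),
                )
            )
            pooled[method].append((scores, labels))
    if config.auc_mode == "pooled":
        rows = {
            m: dict(
                auc=auc_score(
                    np.concatenate([s for s, _ in pooled[m]]),
                    np.concatenate([l for _, l in pooled[m]]),
                ),
                aupr=aupr_score(
                    np.concatenate([s for s, _ in pooled[m]]),
                    np.concatenate([l for _, l in pooled[m]]),
                ),
            )
            for m in METHODS
        }
    else:
        rows = {
            m: dict(
                auc=float(np.mean([r.auc for r in per_fold[m]])),
                aupr=float(np.mean([r.aupr for r in per_fold[m]])),
            )
            for m in METHODS
        }
    table = pd.DataFrame.from_dict(rows, orient="index").loc[list(METHODS)]
    table.index.name = "method"
    table.attrs["learned_weights"] = learned_weights
    table.attrs["seed"] = config.seed
    return table
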