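"""Top-level model: Q-learning fusion of CMF, NRLMF and LapRLS predictions.

`MirnaDiseaseFusion` is built from an association matrix and the two
similarity kernels; `fit()` executes the pipeline — hold out a validation
slice of the known associations, fit the three submodels on the rest, learn
the fusion weight triple by tabular Q-learning on validation AUC — and
returns a `FusionResults` carrying the learned weights, the fused score
matrix, the Q-table and the training history.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .evaluation import fit_submodels, rank_candidates, sample_negatives
from .fusion import QTable, WeightState, fuse, train_fusion


class MirnaDiseaseFusion:
    """Ensemble link-prediction model over a disease x miRNA matrix.

    Parameters
    ----------
    Y : AssociationMatrix or (p, q) binary array
        Known associations.
    disease_sim : SimilarityMatrix or (p, p) array
        Disease semantic similarity kernel, aligned to Y's rows.
    mirna_sim : SimilarityMatrix or (q, q) array
        miRNA functional similarity kernel, aligned to Y's columns.
    config : PipelineConfig
        Parameter blocks of the three submodels and the Q-learner.
    """

    def __init__(self, Y, disease_sim, mirna_sim, config: PipelineConfig | None = None):
        self.Ymat = np.asarray(getattr(Y, "Y", Y), dtype=float)
        self.row_labels = tuple(
            getattr(Y, "row_labels", [f"d{i}" for i in range(self.Ymat.shape[0])])
        )
        self.col_labels = tuple(
            getattr(Y, "col_labels", [f"m{j}" for j in range(self.Ymat.shape[1])])
        )
        self.Sd = np.asarray(getattr(disease_sim, "M", disease_sim), dtype=float)
        self.Sm = np.asarray(getattr(mirna_sim, "M", mirna_sim), dtype=float)
        if self.Sd.shape[0] != self.Ymat.shape[0]:
            raise ValueError("disease similarity size does not match Y rows")
        if self.Sm.shape[0] != self.Ymat.shape[1]:
            raise ValueError("miRNA similarity size does not match Y columns")
        self.config = config or PipelineConfig()

    @classmethod
    def from_frames(
        cls, associations: pd.DataFrame, disease_sim: pd.DataFrame,
        mirna_sim: pd.DataFrame, config: PipelineConfig | None = None,
    ) -> "MirnaDiseaseFusion":
        """Build from a two-column (disease, mirna) DataFrame plus labelled
        similarity DataFrames; similarity frames are aligned by name."""
        from .io import AssociationTable, SimilarityMatrix, build_adjacency
        from .config import align_similarity

        records = [
            (str(d).strip().casefold(), str(m).strip().casefold())
            for d, m in associations.iloc[:, :2].itertuples(index=False)
        ]
        records = list(dict.fromkeys(records))
        diseases = tuple(dict.fromkeys(d for d, _ in records))
        mirnas = tuple(dict.fromkeys(m for _, m in records))
        Y = build_adjacency(AssociationTable(tuple(records), diseases, mirnas))
        Sd = align_similarity(
            SimilarityMatrix(disease_sim.to_numpy(float), tuple(map(str, disease_sim.index))),
            Y.row_labels,
        )
        Sm = align_similarity(
            SimilarityMatrix(mirna_sim.to_numpy(float), tuple(map(str, mirna_sim.index))),
            Y.col_labels,
        )
        return cls(Y, Sd, Sm, config)

    def fit(self, train_pos=None, val_pos=None) -> "FusionResults":
        """Run the pipeline and learn the fusion weights.

        By default the known positives are split (seeded) into a submodel
        training set and a validation set of fraction ``config.val_frac``
        used only for the weight search; pass explicit (row, col) index
        arrays to control the split.
        """
        cfg = self.config
        positives = np.argwhere(self.Ymat == 1)
        if train_pos is None or val_pos is None:
            rng = np.random.default_rng(cfg.seed)
            perm = positives[rng.permutation(len(positives))]
            n_val = max(1, int(round(cfg.val_frac * len(perm))))
            val_pos, train_pos = perm[:n_val], perm[n_val:]
        train_pos = np.asarray(train_pos, dtype=int)
        val_pos = np.asarray(val_pos, dtype=int)
        Y_train = np.zeros_like(self.Ymat)
        Y_train[train_pos[:, 0], train_pos[:, 1]] = 1.0
        F1, F2, F3 = fit_submodels(Y_train, self.Sm, self.Sd, cfg)
        val_neg = sample_negatives(self.Ymat, len(val_pos), seed=cfg.seed + 1)
        state, qtable, history = train_fusion(
            F1, F2, F3, val_pos, val_neg, cfg.qlearn, normalize=False
        )
        refined = None
        if cfg.qlearn.refine:
            from .fusion import refine_weights

            refined = refine_weights(state, F1, F2, F3, val_pos, val_neg)
        return FusionResults(
            model=self,
            weights=state,
            refined_weights=refined,
            qtable=qtable,
            history=pd.DataFrame(history),
            submodel_scores={"CMF": F1, "NRLMF": F2, "LapRLS": F3},
            scores=fuse(F1, F2, F3, state),
            train_pos=train_pos,
            val_pos=val_pos,
        )


@dataclass
class FusionResults:
    """Learned fusion weights plus everything needed to score and rank."""

    model: MirnaDiseaseFusion
    weights: WeightState
    refined_weights: tuple[float, float, float] | None
    qtable: QTable
    history: pd.DataFrame = field(repr=False)
    submodel_scores: dict[str, np.ndarray] = field(repr=False)
    scores: np.ndarray = field(repr=False)
    train_pos: np.ndarray = field(repr=False)
    val_pos: np.ndarray = field(repr=False)

    @property
    def weight_triple(self) -> tuple[float, float, float]:
        return self.refined_weights or self.weights.weights

    @property
    def validation_auc(self) -> float:
        return float(self.history["auc"].max())

    def predict(self) -> np.ndarray:
        """Fused disease x miRNA score matrix F* = a F1 + b F2 + c F3."""
        return self.scores

    def rank(self, disease: str, top_k: int = 50) -> pd.DataFrame:
        """Top candidate miRNAs for one disease, training-known pairs excluded."""
        i = self.model.row_labels.index(disease) if disease in self.model.row_labels else None
        if i is None:
            raise KeyError(f"unknown disease {disease!r}")
        known = {
            self.model.col_labels[j]
            for r, j in self.train_pos
            if r == i
        }
        return rank_candidates(
            self.scores, self.model.row_labels, self.model.col_labels,
            disease, known_pos=known, top_k=top_k,
        )

    def summary(self) -> str:
        a, b, c = self.weights.weights
        lines = [
            "miRNA-disease association fusion (Q-learning ensemble)",
            f"  matrix: {self.model.Ymat.shape[0]} diseases x "
            f"{self.model.Ymat.shape[1]} miRNAs, "
            f"{int(self.model.Ymat.sum())} known associations",
            f"  submodels: CMF, NRLMF, LapRLS (scores min-max normalized)",
            f"  learned weights: a={a:.4f} (CMF), b={b:.4f} (NRLMF), c={c:.4f} (LapRLS)",
            f"  best validation AUC: {self.validation_auc:.4f}",
            f"  Q-table entries: {len(self.qtable)}",
        ]
        if self.refined_weights:
            r = self.refined_weights
            lines.insert(4, f"  refined weights: ({r[0]:.4f}, {r[1]:.4f}, {r[2]:.4f})")
        return "\n".join(lines)
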