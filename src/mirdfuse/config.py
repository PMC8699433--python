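"""Run configuration: parameter blocks, YAML loading, dataset assembly."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .cmf import CmfParams
from .fusion import QLearnParams
from .laprls import LaprlsParams
from .nrlmf import NrlmfParams


@dataclass
class PipelineConfig:
    """All tunables of the end-to-end pipeline, every default explicit."""

    cmf: CmfParams = field(default_factory=CmfParams)
    nrlmf: NrlmfParams = field(default_factory=NrlmfParams)
    laprls: LaprlsParams = field(default_factory=LaprlsParams)
    qlearn: QLearnParams = field(default_factory=QLearnParams)
    delta: float = 0.5  # semantic contribution decay per DAG generation
    folds: int = 5
    seed: int = 0
    auc_mode: str = "mean"  # or "pooled"
    val_frac: float = 0.1

    def __post_init__(self) -> None:
        if self.auc_mode not in ("mean", "pooled"):
            raise ValueError("auc_mode must be 'mean' or 'pooled'")
        if not (0 < self.val_frac < 1):
            raise ValueError("val_frac must lie in (0, 1)")

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        kwargs = {}
        for name, klass in (
            ("cmf", CmfParams),
            ("nrlmf", NrlmfParams),
            ("laprls", LaprlsParams),
            ("qlearn", QLearnParams),
        ):
            block = raw.pop(name, {})
            unknown = set(block) - {f.name for f in dataclasses.fields(klass)}
            if unknown:
                raise ValueError(f"unknown {name} parameters: {sorted(unknown)}")
            kwargs[name] = klass(**block)
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**kwargs, **raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def desk_scale_config(seed: int = 0) -> PipelineConfig:
    """Parameter block sized for desk-scale matrices (tens of rows).

    The library defaults target association matrices with hundreds of rows;
    on small dense synthetic problems a lower latent rank and stronger
    Laplacian smoothing fit better and much faster.  Used by the bundled
    synthetic-study scripts and tests.
    """
    return PipelineConfig(
        cmf=CmfParams(rank=10, seed=seed),
        nrlmf=NrlmfParams(
            rank=5, max_iter=300, learn_rate=0.5, alpha=0.5, beta=0.5, seed=seed
        ),
        laprls=LaprlsParams(),
        qlearn=QLearnParams(episodes=100, steps_per_episode=40, seed=seed),
        seed=seed,
    )


def load_config(path: str | Path) -> tuple[PipelineConfig, dict]:
    """Read a YAML run config; returns (params, data-section dict)."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    data = raw.pop("data", {})
    return PipelineConfig.from_dict(raw.get("params", {}) | {
        k: v for k, v in raw.items() if k != "params"
    }), data


def align_similarity(sim, labels) -> np.ndarray:
    """Reorder a similarity matrix to a reference label order by name."""
    order = []
    index = {name: i for i, name in enumerate(sim.labels)}
    missing = [name for name in labels if name not in index]
    if missing:
        raise KeyError(f"similarity matrix lacks labels: {missing[:5]}")
    order = [index[name] for name in labels]
    return sim.M[np.ix_(order, order)]


def load_dataset(data: dict, config: PipelineConfig):
    """Assemble (Y, disease_sim, mirna_sim) from a config data section.

    Requires ``associations``; disease similarity comes from a precomputed
    matrix (``disease_sim``) or is recomputed from DAGs (``dags``); miRNA
    similarity from ``mirna_sim`` or recomputed by best-match-average.
    Similarity matrices are aligned to the association label order by name.
    """
    from . import io
    from .similarity import disease_similarity_matrix, mirna_functional_similarity

    if "associations" not in data:
        raise ValueError("config data section requires an 'associations' path")
    table = io.load_associations(
        data["associations"], dialect=data.get("dialect", "disease-mirna")
    )
    Y = io.build_adjacency(table)
    if "disease_sim" in data:
        Sd_raw = io.load_similarity_matrix(data["disease_sim"])
    elif "dags" in data:
        dags = io.load_dag_edges(data["dags"])
        Sd_raw = disease_similarity_matrix(dags, config.delta, labels=Y.row_labels)
    else:
        raise ValueError("provide 'disease_sim' or 'dags' in the data section")
    Sd = align_similarity(Sd_raw, Y.row_labels)
    if "mirna_sim" in data:
        Sm = align_similarity(io.load_similarity_matrix(data["mirna_sim"]), Y.col_labels)
    else:
        Sm = mirna_functional_similarity(Y, Sd).M
    return Y, Sd, Sm
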