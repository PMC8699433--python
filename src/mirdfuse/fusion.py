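"""Q-learning of the fusion weights over the three submodel score matrices.

The state is a weight triple (a, b, c) on a discretized 3-simplex with grid
resolution h; actions move one grid step of weight from one submodel to
another (six directed transfers plus STAY).  Each step fuses the three
score matrices with the candidate weights, computes the validation AUC, and
rewards the sign of the AUC change (+1 if it improved, -1 otherwise).  The
Q-table is updated with the standard off-policy Bellman rule; exploration
is epsilon-greedy with per-episode decay.  The returned weights are the
visited state with the highest validation AUC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

_PAIRS = [(d, r) for d in range(3) for r in range(3) if d != r]


@dataclass(frozen=True)
class FusionAction:
    """One of six directed weight transfers (donor -> recipient) or STAY."""

    kind: str  # e.g. "b->a" or "stay"

    def __post_init__(self) -> None:
        if self.kind != "stay" and self.kind not in {
            f"{'abc'[d]}->{'abc'[r]}" for d, r in _PAIRS
        }:
            raise ValueError(f"unknown action {self.kind!r}")


ACTIONS: tuple[FusionAction, ...] = tuple(
    [FusionAction(f"{'abc'[d]}->{'abc'[r]}") for d, r in _PAIRS]
    + [FusionAction("stay")]
)


@dataclass(frozen=True)
class WeightState:
    """A point of the weight simplex on the grid {0, h, 2h, ..., 1}.

    Stored as integer grid units so the simplex constraint holds exactly:
    units sum to resolution N = 1/h and the weights are units/N.
    """

    units: tuple[int, int, int]
    n_units: int

    def __post_init__(self) -> None:
        if min(self.units) < 0 or sum(self.units) != self.n_units:
            raise ValueError(f"units {self.units} do not lie on the simplex grid")

    @classmethod
    def from_weights(cls, a: float, b: float, c: float, h: float) -> "WeightState":
        n = round(1.0 / h)
        units = (round(a * n), round(b * n), round(c * n))
        return cls(units, n)

    @classmethod
    def initial(cls, h: float) -> "WeightState":
        """The equal-weight state, rounded to the grid (residual on c)."""
        n = round(1.0 / h)
        third = round(n / 3)
        return cls((third, third, n - 2 * third), n)

    @property
    def weights(self) -> tuple[float, float, float]:
        return tuple(u / self.n_units for u in self.units)

    @property
    def a(self) -> float:
        return self.units[0] / self.n_units

    @property
    def b(self) -> float:
        return self.units[1] / self.n_units

    @property
    def c(self) -> float:
        return self.units[2] / self.n_units


@dataclass
class QLearnParams:
    """Tabular Q-learning constants.

    h is the simplex grid resolution (1/h must be an integer); alpha_q the
    learning rate; gamma the discount; epsilon the exploration rate, decayed
    multiplicatively per episode.
    """

    h: float = 0.01
    alpha_q: float = 0.1
    gamma: float = 0.9
    epsilon: float = 0.2
    epsilon_decay: float = 0.99
    episodes: int = 200
    steps_per_episode: int = 50
    seed: int = 0
    refine: bool = False

    def __post_init__(self) -> None:
        n = 1.0 / self.h
        if abs(n - round(n)) > 1e-9:
            raise ValueError(f"1/h must be an integer, got h={self.h}")
        if not (0 <= self.alpha_q <= 1):
            raise ValueError("alpha_q must lie in [0, 1]")
        if not (0 <= self.gamma < 1):
            raise ValueError("gamma must lie in [0, 1)")
        if not (0 <= self.epsilon <= 1):
            raise ValueError("epsilon must lie in [0, 1]")


class QTable:
    """Sparse table of Q(state, action) values with visit counts."""

    def __init__(self) -> None:
        self._q: dict[tuple[tuple[int, int, int], int], float] = {}
        self.visits: dict[tuple[tuple[int, int, int], int], int] = {}

    def get(self, state: WeightState, action_idx: int) -> float:
        return self._q.get((state.units, action_idx), 0.0)

    def set(self, state: WeightState, action_idx: int, value: float) -> None:
        if not np.isfinite(value):
            raise ValueError("Q-values must be finite")
        self._q[(state.units, action_idx)] = value

    def max_value(self, state: WeightState) -> float:
        return max(self.get(state, i) for i in range(len(ACTIONS)))

    def best_action(self, state: WeightState) -> int:
        values = [self.get(state, i) for i in range(len(ACTIONS))]
        return int(np.argmax(values))  # first maximizer: deterministic tie-break

    def __len__(self) -> int:
        return len(self._q)

    def items(self):
        return self._q.items()


def apply_action(state: WeightState, action: FusionAction) -> WeightState:
    """Transfer one grid unit between the named weights, clipping at zero.

    If the donor weight would go negative the action is a no-op; the total
    is preserved exactly in either case.
    """
    if action.kind == "stay":
        return state
    donor = "abc".index(action.kind[0])
    recip = "abc".index(action.kind[3])
    units = list(state.units)
    if units[donor] < 1:
        return state
    units[donor] -= 1
    units[recip] += 1
    return WeightState(tuple(units), state.n_units)


def minmax_normalize(F: np.ndarray) -> np.ndarray:
    """Rescale a score matrix to [0, 1]; a constant matrix maps to zeros."""
    lo, hi = float(F.min()), float(F.max())
    if hi - lo <= 0:
        return np.zeros_like(F)
    return (F - lo) / (hi - lo)


def fuse(F1: np.ndarray, F2: np.ndarray, F3: np.ndarray, state: WeightState) -> np.ndarray:
    """Convex combination a*F1 + b*F2 + c*F3 of pre-normalized score matrices."""
    if not (F1.shape == F2.shape == F3.shape):
        raise ValueError("score matrices must share a shape")
    a, b, c = state.weights
    return a * F1 + b * F2 + c * F3


def reward(auc_next: float, auc_cur: float) -> int:
    """+1 if the validation AUC strictly improved, else -1 (ties score -1)."""
    return 1 if auc_next - auc_cur > 0 else -1


def q_update(
    q: QTable,
    state: WeightState,
    action_idx: int,
    r: float,
    state_next: WeightState,
    params: QLearnParams,
) -> QTable:
    """Off-policy Bellman update:
    Q(s,a) += alpha_q * (r + gamma * max_a' Q(s',a') - Q(s,a))."""
    old = q.get(state, action_idx)
    target = r + params.gamma * q.max_value(state_next)
    q.set(state, action_idx, old + params.alpha_q * (target - old))
    q.visits[(state.units, action_idx)] = q.visits.get((state.units, action_idx), 0) + 1
    return q


def train_fusion(
    F1: np.ndarray,
    F2: np.ndarray,
    F3: np.ndarray,
    val_pos,
    val_neg,
    params: QLearnParams | None = None,
    normalize: bool = True,
):
    """Learn fusion weights by epsilon-greedy tabular Q-learning.

    Parameters
    ----------
    F1, F2, F3
        Submodel score matrices (same shape).  Min-max normalized to [0, 1]
        per matrix unless ``normalize=False`` (then they must already be on
        a common scale).
    val_pos, val_neg
        Sequences of (row, col) index pairs: validation positives and
        sampled validation negatives.  Must be disjoint from the submodels'
        training positives.
    params : QLearnParams

    Returns
    -------
    (best_state, qtable, history)
        ``best_state`` is the visited state with the highest validation
        AUC; ``history`` is a list of dict rows (episode, step, a, b, c,
        auc, reward) suitable for a DataFrame.
    """
    from .evaluation import auc_score

    params = params or QLearnParams()
    if normalize:
        F1, F2, F3 = minmax_normalize(F1), minmax_normalize(F2), minmax_normalize(F3)
    val_pos = np.asarray(list(val_pos), dtype=int)
    val_neg = np.asarray(list(val_neg), dtype=int)
    if val_pos.size == 0:
        raise ValueError("validation positives are empty")
    rows = np.concatenate([val_pos[:, 0], val_neg[:, 0]])
    cols = np.concatenate([val_pos[:, 1], val_neg[:, 1]])
    labels = np.concatenate([np.ones(len(val_pos)), np.zeros(len(val_neg))])
    f1, f2, f3 = F1[rows, cols], F2[rows, cols], F3[rows, cols]

    auc_cache: dict[tuple[int, int, int], float] = {}

    def auc_of(state: WeightState) -> float:
        key = state.units
        if key not in auc_cache:
            a, b, c = state.weights
            auc_cache[key] = auc_score(a * f1 + b * f2 + c * f3, labels)
        return auc_cache[key]

    rng = np.random.default_rng(params.seed)
    q = QTable()
    s0 = WeightState.initial(params.h)
    auc0 = auc_of(s0)
    history: list[dict] = [
        dict(episode=-1, step=-1, a=s0.a, b=s0.b, c=s0.c, auc=auc0, reward=0)
    ]
    best_state, best_auc = s0, auc0
    eps = params.epsilon
    for episode in range(params.episodes):
        state, auc_cur = s0, auc0
        for step in range(params.steps_per_episode):
            if rng.random() < eps:
                action_idx = int(rng.integers(len(ACTIONS)))
            else:
                action_idx = q.best_action(state)
            state_next = apply_action(state, ACTIONS[action_idx])
            auc_next = auc_of(state_next)
            r = reward(auc_next, auc_cur)
            q_update(q, state, action_idx, r, state_next, params)
            history.append(
                dict(
                    episode=episode,
                    step=step,
                    a=state_next.a,
                    b=state_next.b,
                    c=state_next.c,
                    auc=auc_next,
                    reward=r,
                )
            )
            if auc_next > best_auc:
                best_state, best_auc = state_next, auc_next
            state, auc_cur = state_next, auc_next
        eps *= params.epsilon_decay
    logger.info(
        "Q-learning visited %d states; best validation AUC %.4f at weights %s",
        len(auc_cache),
        best_auc,
        tuple(round(w, 4) for w in best_state.weights),
    )
    return best_state, q, history


def refine_weights(
    state: WeightState,
    F1: np.ndarray,
    F2: np.ndarray,
    F3: np.ndarray,
    val_pos,
    val_neg,
    sweeps: int = 2,
    grid: int = 40,
) -> tuple[float, float, float]:
    """Continuous local refinement of a grid state (post-processing only).

    Sweeps each weight pair, holding the third weight fixed, over a fine
    line search maximizing validation AUC.  Returns a weight triple off the
    Q-learning grid (4-decimal resolution); the Q-learning result itself is
    untouched.
    """
    from .evaluation import auc_score

    val_pos = np.asarray(list(val_pos), dtype=int)
    val_neg = np.asarray(list(val_neg), dtype=int)
    rows = np.concatenate([val_pos[:, 0], val_neg[:, 0]])
    cols = np.concatenate([val_pos[:, 1], val_neg[:, 1]])
    labels = np.concatenate([np.ones(len(val_pos)), np.zeros(len(val_neg))])
    f = np.stack([F1[rows, cols], F2[rows, cols], F3[rows, cols]])
    w = np.array(state.weights)

    def score(weights: np.ndarray) -> float:
        return auc_score(weights @ f, labels)

    for _ in range(sweeps):
        for i, j in ((0, 1), (0, 2), (1, 2)):
            total = w[i] + w[j]
            if total <= 0:
                continue
            ts = np.linspace(0.0, total, grid + 1)
            best_t, best_v = w[i], score(w)
            for t in ts:
                cand = w.copy()
                cand[i], cand[j] = t, total - t
                v = score(cand)
                if v > best_v:
                    best_t, best_v = t, v
            w[i], w[j] = best_t, total - best_t
    w = np.round(w / w.sum(), 4)
    w[2] = round(1.0 - w[0] - w[1], 4)
    return tuple(w)
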