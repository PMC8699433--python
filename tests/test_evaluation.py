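"""Folds, ranking metrics against brute-force oracles, candidate ranking."""

import numpy as np
import pytest

from mirdfuse.evaluation import (
    EvalResult,
    auc_score,
    aupr_score,
    evaluate_pipeline,
    make_folds,
    rank_candidates,
    sample_negatives,
)


def auc_pair_counting(scores, labels):
    """O(n^2) Mann-Whitney oracle: P(pos > neg) + 0.5 P(tie)."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def aupr_threshold_sweep(scores, labels):
    """Exhaustive threshold sweep: step-wise sum of precision * recall gain."""
    order = np.argsort(-np.asarray(scores, dtype=float), kind="stable")
    labels = np.asarray(labels, dtype=float)[order]
    scores = np.asarray(scores, dtype=float)[order]
    n_pos = labels.sum()
    area, tp, prev_recall = 0.0, 0.0, 0.0
    i = 0
    n = len(labels)
    while i < n:
        j = i
        while j < n and scores[j] == scores[i]:  # process tied block at once
            j += 1
        tp += labels[i:j].sum()
        precision = tp / j
        recall = tp / n_pos
        area += precision * (recall - prev_recall)
        prev_recall = recall
        i = j
    return area


class TestMakeFolds:
    def make_y(self, n_pos, shape=(6, 6), seed=0):
        rng = np.random.default_rng(seed)
        Y = np.zeros(shape)
        idx = rng.choice(shape[0] * shape[1], size=n_pos, replace=False)
        Y.ravel()[idx] = 1
        return Y

    def test_ten_positives_five_folds_test_size_two(self):
        folds = make_folds(self.make_y(10), k=5, seed=1)
        assert [len(f.test_pos) for f in folds] == [2, 2, 2, 2, 2]

    def test_test_sets_partition_positives(self):
        Y = self.make_y(23, shape=(8, 8))
        folds = make_folds(Y, k=5, seed=3)
        all_test = np.concatenate([f.test_pos for f in folds])
        assert len(all_test) == 23
        assert len({tuple(r) for r in all_test}) == 23
        for f in folds:
            sets = [
                {tuple(r) for r in part}
                for part in (f.train_pos, f.val_pos, f.test_pos)
            ]
            assert not (sets[0] & sets[1] or sets[0] & sets[2] or sets[1] & sets[2])
            assert len(sets[0] | sets[1] | sets[2]) == 23

    def test_train_val_ratio_is_eight_to_one(self):
        folds = make_folds(self.make_y(45, shape=(10, 10)), k=5, seed=0)
        for f in folds:
            rest = len(f.train_pos) + len(f.val_pos)
            assert len(f.val_pos) == max(1, round(rest / 9))

    def test_same_seed_identical_folds(self):
        Y = self.make_y(12)
        f1 = make_folds(Y, k=4, seed=7)
        f2 = make_folds(Y, k=4, seed=7)
        for a, b in zip(f1, f2):
            np.testing.assert_array_equal(a.train_pos, b.train_pos)
            np.testing.assert_array_equal(a.test_pos, b.test_pos)

    def test_too_few_positives_rejected(self):
        with pytest.raises(ValueError):
            make_folds(self.make_y(3), k=5)


class TestAucScore:
    def test_perfect_separation(self):
        assert auc_score([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_perfect_inversion(self):
        assert auc_score([0.1, 0.2, 0.8, 0.9], [1, 1, 0, 0]) == 0.0

    def test_example_then_one_flip(self):
        assert auc_score([0.9, 0.4, 0.6, 0.2], [1, 0, 1, 0]) == 1.0
        flipped = [1, 0, 0, 1]
        assert auc_score([0.9, 0.4, 0.6, 0.2], flipped) == pytest.approx(
            auc_pair_counting([0.9, 0.4, 0.6, 0.2], flipped)
        )

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.choice([0.1, 0.25, 0.5, 0.8], size=20)  # force ties
        labels = rng.integers(0, 2, size=20)
        if labels.sum() in (0, 20):
            labels[0] = 1 - labels[0]
        assert auc_score(scores, labels) == pytest.approx(
            auc_pair_counting(scores, labels), abs=1e-12
        )

    def test_monotone_transform_invariance(self, rng):
        scores = rng.random(30)
        labels = rng.integers(0, 2, size=30)
        labels[0], labels[1] = 0, 1
        assert auc_score(np.exp(5 * scores), labels) == pytest.approx(
            auc_score(scores, labels), abs=1e-12
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc_score([0.5, 0.6], [1, 1])


class TestAuprScore:
    def test_perfect_ranking_is_one(self):
        assert aupr_score([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_equal_scores_give_prevalence(self):
        labels = [1, 0, 0, 1, 0]
        assert aupr_score([0.5] * 5, labels) == pytest.approx(2 / 5)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_threshold_sweep_oracle(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.choice([0.1, 0.3, 0.6, 0.9], size=10)
        labels = rng.integers(0, 2, size=10)
        if labels.sum() == 0:
            labels[0] = 1
        assert aupr_score(scores, labels) == pytest.approx(
            aupr_threshold_sweep(scores, labels), abs=1e-12
        )

    def test_monotone_transform_invariance(self, rng):
        scores = rng.random(25)
        labels = rng.integers(0, 2, size=25)
        labels[0] = 1
        assert aupr_score(scores**3, labels) == pytest.approx(
            aupr_score(scores, labels), abs=1e-12
        )

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError):
            aupr_score([0.5, 0.6], [0, 0])


class TestRankCandidates:
    F = np.array([[0.9, 0.5, 0.7, 0.5], [0.1, 0.2, 0.3, 0.4]])
    rows = ("d1", "d2")
    cols = ("m1", "m2", "m3", "m4")

    def test_sorted_descending_with_ranks(self):
        table = rank_candidates(self.F, self.rows, self.cols, "d1")
        assert list(table["mirna"]) == ["m1", "m3", "m2", "m4"]
        assert list(table["rank"]) == [1, 2, 3, 4]

    def test_ties_broken_lexicographically(self):
        table = rank_candidates(self.F, self.rows, self.cols, "d1")
        # m2 and m4 tie at 0.5; m2 sorts first
        assert list(table["mirna"])[2:] == ["m2", "m4"]

    def test_known_positives_excluded(self):
        table = rank_candidates(self.F, self.rows, self.cols, "d1", known_pos={"m1", "m3"})
        assert set(table["mirna"]) == {"m2", "m4"}

    def test_top_k_truncation(self):
        table = rank_candidates(self.F, self.rows, self.cols, "d1", top_k=2)
        assert len(table) == 2

    def test_unknown_disease_key_error(self):
        with pytest.raises(KeyError):
            rank_candidates(self.F, self.rows, self.cols, "nope")


class TestSampleNegatives:
    def test_only_unknown_pairs_sampled(self, rng):
        Y = (rng.random((6, 6)) < 0.4).astype(float)
        neg = sample_negatives(Y, 8, seed=0)
        assert all(Y[i, j] == 0 for i, j in neg)
        assert len({tuple(r) for r in neg}) == len(neg)


class TestEvaluatePipeline:
    def test_table_shape_and_planted_ordering(self, small_dataset):
        from mirdfuse.config import desk_scale_config

        Y, Sd, Sm, _ = small_dataset
        cfg = desk_scale_config(seed=2)
        cfg.folds = 3
        cfg.qlearn.episodes = 20
        cfg.qlearn.steps_per_episode = 20
        cfg.nrlmf.max_iter = 100
        table = evaluate_pipeline((Y, Sd, Sm), cfg)
        assert list(table.index) == ["CMF", "NRLMF", "LapRLS", "Mean-Weighted", "Q-Fusion"]
        assert list(table.columns) == ["auc", "aupr"]
        assert ((table >= 0) & (table <= 1)).all().all()
        # planted structure is learnable: everything clearly above chance
        assert (table["auc"] > 0.7).all()

    def test_label_shuffled_data_is_chance_level(self):
        rng = np.random.default_rng(0)
        from mirdfuse.config import desk_scale_config

        Y = np.zeros((30, 30))
        idx = rng.choice(900, size=90, replace=False)
        Y.ravel()[idx] = 1  # positives placed uniformly at random
        Sd = rng.random((30, 30))
        Sd = (Sd + Sd.T) / 2
        np.fill_diagonal(Sd, 1)
        Sm = rng.random((30, 30))
        Sm = (Sm + Sm.T) / 2
        np.fill_diagonal(Sm, 1)
        cfg = desk_scale_config(seed=0)
        cfg.folds = 3
        cfg.qlearn.episodes = 10
        cfg.qlearn.steps_per_episode = 10
        cfg.nrlmf.max_iter = 60
        table = evaluate_pipeline((Y, Sd, Sm), cfg)
        assert (abs(table["auc"] - 0.5) < 0.15).all()

    def test_pooled_mode_also_runs(self, small_dataset):
        from mirdfuse.config import desk_scale_config

        Y, Sd, Sm, _ = small_dataset
        cfg = desk_scale_config(seed=2)
        cfg.folds = 2
        cfg.auc_mode = "pooled"
        cfg.qlearn.episodes = 5
        cfg.qlearn.steps_per_episode = 10
        cfg.nrlmf.max_iter = 40
        table = evaluate_pipeline((Y, Sd, Sm), cfg)
        assert table.shape == (5, 2)
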