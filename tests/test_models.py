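"""Classifier training and the six evaluation metrics against oracles."""

import numpy as np
import pytest

from epilink.models import (
    ClassifierSpec,
    PairClassifier,
    compute_metrics,
    confusion_at_threshold,
    cross_validate,
    evaluate_transfer,
    train,
)

# --- independent oracles -------------------------------------------------

def mann_whitney_auc(scores, labels):
    """Tie-aware pair-counting AUC: P(pos > neg) + 0.5 P(pos == neg)."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def exhaustive_auprc(scores, labels):
    """Step-wise PR area over every distinct score threshold."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    n_pos = int(labels.sum())
    area, prev_recall = 0.0, 0.0
    for t in sorted(set(scores), reverse=True):
        pred = scores >= t
        tp = int(np.sum(pred & (labels == 1)))
        fp = int(np.sum(pred & (labels == 0)))
        recall = tp / n_pos
        precision = tp / (tp + fp)
        area += (recall - prev_recall) * precision
        prev_recall = recall
    return area


# --- metric formula checks ----------------------------------------------

SCORES = np.array([0.9, 0.8, 0.4, 0.6, 0.2, 0.1, 0.1, 0.05, 0.05, 0.3])
LABELS = np.array([1, 1, 1, 0, 0, 0, 0, 0, 0, 0])


class TestConfusion:
    def test_hand_count(self):
        c = confusion_at_threshold(SCORES, LABELS, 0.5)
        assert (c.TP, c.FN, c.FP, c.TN) == (2, 1, 1, 6)
        assert c.total == 10

    def test_extreme_thresholds(self):
        all_pos = confusion_at_threshold(SCORES, LABELS, 0.0)
        assert all_pos.FN == 0 and all_pos.TN == 0
        all_neg = confusion_at_threshold(SCORES, LABELS, 1.1)
        assert all_neg.TP == 0 and all_neg.FP == 0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion_at_threshold(SCORES[:5], LABELS)


class TestMetrics:
    def test_formulas_on_hand_counted_confusion(self):
        # TP=2, FP=1, FN=1, TN=6
        m = compute_metrics(SCORES, LABELS, 0.5)
        assert m.sn == pytest.approx(2 / 3)
        assert m.sp == pytest.approx(6 / 7)
        assert m.precision == pytest.approx(2 / 3)
        assert m.acc == pytest.approx(0.8)

    def test_perfect_ranking(self):
        m = compute_metrics([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert m.auc == 1.0 and m.auprc == 1.0

    def test_tied_scores_auc(self):
        # pos {0.8, 0.5}, neg {0.5, 0.2}: pair wins 3.5 of 4 -> 0.875
        scores, labels = [0.8, 0.5, 0.5, 0.2], [1, 1, 0, 0]
        assert mann_whitney_auc(scores, labels) == 0.875
        assert compute_metrics(scores, labels).auc == pytest.approx(0.875)

    @pytest.mark.parametrize("seed", range(20))
    def test_auc_matches_mann_whitney_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 51))
        labels = np.zeros(n, int)
        labels[: max(1, n // 5)] = 1
        rng.shuffle(labels)
        # coarse grid forces plenty of ties
        scores = rng.integers(0, 6, size=n) / 5.0
        got = compute_metrics(scores, labels).auc
        assert got == pytest.approx(mann_whitney_auc(scores, labels), abs=1e-12)

    @pytest.mark.parametrize("seed", range(20))
    def test_auprc_matches_exhaustive_threshold_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(4, 51))
        labels = np.zeros(n, int)
        labels[: max(1, n // 5)] = 1
        rng.shuffle(labels)
        scores = rng.integers(0, 6, size=n) / 5.0
        got = compute_metrics(scores, labels).auprc
        assert got == pytest.approx(exhaustive_auprc(scores, labels), abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_rank_metrics_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(200 + seed)
        labels = rng.integers(0, 2, size=40)
        labels[:2] = [0, 1]
        scores = rng.random(40)
        a = compute_metrics(scores, labels)
        b = compute_metrics(1 / (1 + np.exp(-7 * scores + 2)), labels)
        assert a.auc == pytest.approx(b.auc, abs=1e-12)
        assert a.auprc == pytest.approx(b.auprc, abs=1e-12)

    def test_acc_is_prevalence_weighted_sn_sp(self):
        rng = np.random.default_rng(5)
        labels = rng.integers(0, 2, size=100)
        labels[:2] = [0, 1]
        scores = rng.random(100)
        m = compute_metrics(scores, labels)
        P, N = labels.sum(), (1 - labels).sum()
        assert m.acc == pytest.approx((m.sn * P + m.sp * N) / (P + N), abs=1e-12)
        # Sn*(TP+FN) and Sp*(TN+FP) recover integer counts
        assert m.sn * P == pytest.approx(round(m.sn * P), abs=1e-9)
        assert m.sp * N == pytest.approx(round(m.sp * N), abs=1e-9)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="one class"):
            compute_metrics([0.1, 0.9], [1, 1])


# --- training ------------------------------------------------------------

def _separable(n=40, d=12):
    X = np.vstack([np.ones((n // 2, d)), np.zeros((n // 2, d))])
    y = np.array([1] * (n // 2) + [0] * (n // 2))
    return X, y


class TestTraining:
    @pytest.mark.parametrize("algo", ["RF", "AdaBoost", "GBDT"])
    def test_separable_data_perfect_training_auc(self, algo):
        X, y = _separable()
        model = train(X, y, ClassifierSpec(algo=algo, seed=0))
        assert compute_metrics(model.scores(X), y).auc == 1.0

    def test_same_seed_identical_predictions(self):
        rng = np.random.default_rng(0)
        X = rng.random((60, 10))
        y = (X[:, 0] + 0.3 * rng.random(60) > 0.6).astype(int)
        s1 = train(X, y, ClassifierSpec(seed=42)).scores(X)
        s2 = train(X, y, ClassifierSpec(seed=42)).scores(X)
        np.testing.assert_array_equal(s1, s2)

    def test_training_auc_dominates_heldout_on_average(self):
        # planted weak signal: training fit should not generalise better
        gaps = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(80, 20))
            y = (X[:, 0] + rng.normal(scale=2.0, size=80) > 0).astype(int)
            if len(np.unique(y[:40])) < 2 or len(np.unique(y[40:])) < 2:
                continue
            model = train(X[:40], y[:40], ClassifierSpec(seed=seed))
            auc_tr = compute_metrics(model.scores(X[:40]), y[:40]).auc
            auc_te = compute_metrics(model.scores(X[40:]), y[40:]).auc
            gaps.append(auc_tr - auc_te)
        assert np.mean(gaps) >= 0

    def test_single_class_training_rejected(self):
        X = np.random.default_rng(0).random((10, 3))
        with pytest.raises(ValueError):
            train(X, np.ones(10, int), ClassifierSpec())

    def test_persistence_round_trip(self, tmp_path):
        X, y = _separable()
        model = train(X, y, ClassifierSpec(seed=1), schema_hash="abc123")
        model.save(tmp_path / "m.joblib")
        back = PairClassifier.load(tmp_path / "m.joblib")
        assert back.schema_hash == "abc123"
        np.testing.assert_array_equal(back.scores(X), model.scores(X))


class TestCrossValidate:
    def _data(self):
        rng = np.random.default_rng(1)
        X = rng.random((50, 8))
        y = np.array([1] * 10 + [0] * 40)
        return X, y

    def test_fold_structure(self):
        X, y = self._data()
        folds, mean = cross_validate(X, y, ClassifierSpec(seed=0), k=10)
        assert len(folds) == 10
        assert all(0 <= v <= 1 for v in mean.as_dict().values())

    def test_folds_partition_and_stratify(self):
        from sklearn.model_selection import StratifiedKFold

        X, y = self._data()
        skf = StratifiedKFold(n_splits=10, shuffle=True, random_state=0)
        seen = []
        for _, val in skf.split(X, y):
            assert y[val].sum() == 1 and len(val) == 5  # 1 pos + 4 neg per fold
            seen.extend(val.tolist())
        assert sorted(seen) == list(range(50))

    def test_same_seed_same_folds(self):
        X, y = self._data()
        _, m1 = cross_validate(X, y, ClassifierSpec(seed=5), k=5)
        _, m2 = cross_validate(X, y, ClassifierSpec(seed=5), k=5)
        assert m1 == m2

    def test_too_few_class_members(self):
        X, y = self._data()
        with pytest.raises(ValueError, match="class"):
            cross_validate(X, y, ClassifierSpec(), k=11)


class TestTransfer:
    def test_self_transfer_equals_in_sample(self):
        X, y = _separable()
        model = train(X, y, ClassifierSpec(seed=0), schema_hash="h")
        a = evaluate_transfer(model, X, y, schema_hash="h")
        b = compute_metrics(model.scores(X), y)
        assert a == b

    def test_schema_mismatch_refused(self):
        X, y = _separable()
        model = train(X, y, ClassifierSpec(seed=0), schema_hash="h1")
        with pytest.raises(ValueError, match="schema"):
            evaluate_transfer(model, X, y, schema_hash="h2")

    def test_permuted_labels_score_near_chance(self):
        rng = np.random.default_rng(0)
        X = rng.random((200, 10))
        y = (X[:, 0] > 0.5).astype(int)
        model = train(X, y, ClassifierSpec(seed=0))
        scores = model.scores(X)
        null_aucs = []
        for _ in range(100):
            perm = rng.permutation(y)
            if len(np.unique(perm)) < 2:
                continue
            null_aucs.append(compute_metrics(scores, perm).auc)
        assert abs(np.mean(null_aucs) - 0.5) < 0.02
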