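"""Splits, k-fold, metrics against brute-force tallies, ROC against the
Mann-Whitney formulation, and mean-ROC averaging."""

import itertools

import numpy as np
import pytest

from ctgkit.evaluate import (
    ROCCurve,
    SklearnPredictor,
    SplitSpec,
    compute_metrics,
    evaluate_model,
    kfold,
    mean_roc,
    roc_curve_auc,
    split_dataset,
)


def oracle_metrics(y_true, y_pred):
    """Plain confusion-table counting for the weighted report."""
    n = len(y_true)
    acc = sum(t == p for t, p in zip(y_true, y_pred)) / n
    per = {}
    for c in (0, 1):
        tp = sum(1 for t, p in zip(y_true, y_pred) if t == c and p == c)
        fp = sum(1 for t, p in zip(y_true, y_pred) if t != c and p == c)
        fn = sum(1 for t, p in zip(y_true, y_pred) if t == c and p != c)
        sup = tp + fn
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / sup if sup else float("nan")
        f1 = 2 * prec * rec / (prec + rec) if sup and prec + rec else (
            0.0 if sup else float("nan"))
        per[c] = (prec if sup else float("nan"), rec, f1, sup)
    total = sum(per[c][3] for c in (0, 1))
    w = lambda k: sum(per[c][k] * per[c][3] for c in (0, 1) if per[c][3]) / total
    return acc, per, w(0), w(1), w(2)


def mann_whitney_auc(y_true, scores):
    """AUC = P(score+ > score-) + 0.5 P(tie)."""
    pos = [s for s, t in zip(scores, y_true) if t == 1]
    neg = [s for s, t in zip(scores, y_true) if t == 0]
    wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


class TestSplitDataset:
    def test_default_sizes_n1000(self):
        y = np.array([0, 1] * 500)
        tr, te, va = split_dataset(y, SplitSpec(seed=0))
        assert (len(tr), len(te), len(va)) == (600, 200, 200)

    def test_stratified_small_n(self):
        y = np.array([0] * 5 + [1] * 5)
        tr, te, va = split_dataset(y, SplitSpec(seed=1))
        for part in (tr, te, va):
            assert set(y[part]) == {0, 1}

    def test_disjoint_exhaustive(self):
        y = np.array([0, 1] * 50)
        tr, te, va = split_dataset(y, SplitSpec(seed=2))
        allidx = np.concatenate([tr, te, va])
        assert len(np.unique(allidx)) == len(y)
        assert set(tr) & set(te) == set()
        assert set(tr) & set(va) == set()

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            SplitSpec(train_fraction=0.5, test_fraction=0.2,
                      validation_fraction=0.2)

    def test_class_proportions_within_one_sample(self):
        y = np.array([0] * 70 + [1] * 30)
        tr, te, va = split_dataset(y, SplitSpec(seed=3))
        for part, frac in ((tr, 0.6), (te, 0.2), (va, 0.2)):
            n1 = int(np.sum(y[part]))
            assert abs(n1 - 30 * frac) <= 1


class TestKFold:
    def test_each_record_exactly_one_test_fold(self):
        y = np.array([0, 1] * 25)
        folds = kfold(y, k=5, seed=0)
        test_idx = np.concatenate([te for _, te in folds])
        assert sorted(test_idx) == list(range(len(y)))

    def test_each_record_in_four_training_folds(self):
        y = np.array([0, 1] * 5)
        folds = kfold(y, k=5, seed=0)
        counts = np.zeros(len(y), dtype=int)
        for tr, _ in folds:
            counts[tr] += 1
        assert np.all(counts == 4)

    def test_reproducible_from_seed(self):
        y = np.array([0, 1] * 20)
        a = kfold(y, k=5, seed=4)
        b = kfold(y, k=5, seed=4)
        for (tra, tea), (trb, teb) in zip(a, b):
            assert np.array_equal(tra, trb) and np.array_equal(tea, teb)

    def test_k_exceeding_n_rejected(self):
        with pytest.raises(ValueError):
            kfold(np.array([0, 1]), k=5)


class TestComputeMetrics:
    def test_perfect_prediction(self):
        m = compute_metrics([0, 1, 0, 1], [0, 1, 0, 1])
        assert m.accuracy == 1.0 and m.avg_f1 == 1.0

    def test_hand_counted_confusion_table(self):
        m = compute_metrics([0, 0, 1, 1], [0, 1, 1, 1])
        assert m.precision[1] == pytest.approx(2 / 3)
        assert m.recall[1] == 1.0
        assert m.accuracy == 0.75

    def test_label_swap_symmetry(self):
        y_true = [0, 0, 1, 1, 0]
        y_pred = [0, 1, 1, 0, 0]
        a = compute_metrics(y_true, y_pred)
        b = compute_metrics([1 - t for t in y_true], [1 - p for p in y_pred])
        assert a.accuracy == b.accuracy
        assert a.avg_f1 == pytest.approx(b.avg_f1)

    def test_absent_class_gets_nan_and_zero_weight(self):
        m = compute_metrics([0, 0, 0], [0, 1, 0])
        assert np.isnan(m.recall[1])
        assert not np.isnan(m.avg_recall)

    def test_matches_sklearn_report(self, rng):
        from sklearn.metrics import precision_recall_fscore_support

        for _ in range(20):
            y_true = rng.integers(0, 2, 30)
            y_pred = rng.integers(0, 2, 30)
            if len(np.unique(y_true)) < 2:
                continue
            m = compute_metrics(y_true, y_pred)
            p, r, f, _ = precision_recall_fscore_support(
                y_true, y_pred, average="weighted", zero_division=0
            )
            assert m.avg_recall == pytest.approx(r)
            assert m.accuracy == pytest.approx((y_true == y_pred).mean())

    def test_exhaustive_short_vectors_match_oracle(self):
        for n in range(2, 7):
            for y_true in itertools.product((0, 1), repeat=n):
                if len(set(y_true)) < 2:
                    continue
                for y_pred in itertools.product((0, 1), repeat=n):
                    m = compute_metrics(y_true, y_pred)
                    acc, per, wp, wr, wf = oracle_metrics(y_true, y_pred)
                    assert m.accuracy == pytest.approx(acc)
                    assert m.avg_precision == pytest.approx(wp)
                    assert m.avg_f1 == pytest.approx(wf)


class TestROC:
    def test_perfect_and_antiperfect_auc(self):
        y = [0, 0, 1, 1]
        assert roc_curve_auc(y, [0.1, 0.2, 0.8, 0.9]).auc == 1.0
        assert roc_curve_auc(y, [0.9, 0.8, 0.2, 0.1]).auc == 0.0

    def test_reflection_identity(self, rng):
        y = rng.integers(0, 2, 50)
        y[:2] = [0, 1]
        s = rng.normal(size=50)
        assert roc_curve_auc(y, s).auc + roc_curve_auc(y, -s).auc == pytest.approx(1.0)

    def test_matches_mann_whitney_with_ties(self, rng):
        for _ in range(20):
            y = rng.integers(0, 2, 20)
            if len(np.unique(y)) < 2:
                continue
            s = rng.integers(0, 5, 20).astype(float)  # many ties
            assert roc_curve_auc(y, s).auc == pytest.approx(
                mann_whitney_auc(y, s)
            )

    def test_random_scores_near_half(self, rng):
        y = rng.integers(0, 2, 4000)
        s = rng.normal(size=4000)
        assert abs(roc_curve_auc(y, s).auc - 0.5) < 0.05

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_curve_auc([1, 1, 1], [0.1, 0.2, 0.3])


class TestMeanROC:
    def test_identical_curves_unchanged(self):
        c = roc_curve_auc([0, 0, 1, 1], [0.1, 0.4, 0.35, 0.8])
        m = mean_roc([c, c, c])
        assert m.auc == pytest.approx(c.auc)
        # interior grid points match the member; endpoints are pinned to
        # (0,0) and (1,1) by the averaging convention
        interp = np.interp(m.fpr, c.fpr, c.tpr)
        assert np.allclose(interp[1:-1], m.tpr[1:-1], atol=1e-9)

    def test_mean_auc_is_arithmetic_mean(self):
        a = ROCCurve(np.array([0, 1.0]), np.array([0, 1.0]), 0.4)
        b = ROCCurve(np.array([0, 1.0]), np.array([0, 1.0]), 0.6)
        assert mean_roc([a, b]).auc == pytest.approx(0.5)

    def test_mean_within_member_envelope(self, rng):
        curves = []
        for _ in range(5):
            y = rng.integers(0, 2, 40)
            y[:2] = [0, 1]
            curves.append(roc_curve_auc(y, rng.normal(size=40)))
        m = mean_roc(curves)
        tprs = np.array([np.interp(m.fpr, c.fpr, c.tpr) for c in curves])
        assert np.all(m.tpr <= tprs.max(axis=0) + 1e-9)
        assert np.all(m.tpr >= tprs.min(axis=0) - 1e-9)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            mean_roc([])


class TestEvaluateModel:
    def test_kfold_report_has_five_folds(self, rng):
        from sklearn.linear_model import LogisticRegression

        X = rng.normal(size=(60, 3))
        y = (X[:, 0] > 0).astype(int)
        rep = evaluate_model(
            lambda: SklearnPredictor(lambda: LogisticRegression()),
            X, y, protocol="kfold5", seed=0,
        )
        assert len(rep.folds) == 5
        assert rep.to_frame().shape[0] == 5

    def test_perfect_predictor_perfect_folds(self):
        class Oracle:
            def fit(self, X, y):
                return self

            def predict(self, X):
                return (X[:, 0] > 0).astype(int)

            def score(self, X):
                return X[:, 0]

        rng = np.random.default_rng(0)
        X = rng.normal(size=(50, 2))
        y = (X[:, 0] > 0).astype(int)
        rep = evaluate_model(lambda: Oracle(), X, y, protocol="kfold5", seed=0)
        assert all(f["metrics"].accuracy == 1.0 for f in rep.folds)
        assert rep.mean_roc.auc == pytest.approx(1.0)
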