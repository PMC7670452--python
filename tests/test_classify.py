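"""LDC fitting, holdout splitting, metrics and the 2-step scheme."""

import numpy as np
import pytest

from hdsemg import (compute_metrics, fit_ldc, predict_ldc, repeated_holdout,
                    classify_tasks, classify_task_effort, compare_feature_sets)
from hdsemg.classify import (acc_from_counts, composite_label,
                             confusion_counts, f1_from_counts, TASK_MUSCLES)
from hdsemg.features import FeatureSet


def _gaussian_classes(rng, means, n_per, sd=1.0):
    X, y = [], []
    for label, mu in means.items():
        X.append(rng.normal(mu, sd, size=(n_per, len(mu))))
        y += [label] * n_per
    return np.vstack(X), np.array(y)


class TestLdc:
    def test_separable_classes_zero_test_error(self, rng):
        X, y = _gaussian_classes(rng, {"a": [0, 0], "b": [10, 10]}, 100)
        tr = np.r_[0:70, 100:170]
        te = np.setdiff1d(np.arange(200), tr)
        model = fit_ldc(X[tr], y[tr])
        pred, _ = predict_ldc(model, X[te])
        assert (pred == y[te]).all()

    def test_identical_distributions_near_chance(self, rng):
        X = rng.normal(size=(400, 3))
        y = np.array(["a", "b"] * 200)
        model = fit_ldc(X[:300], y[:300])
        pred, scores = predict_ldc(model, X[300:])
        m = compute_metrics(y[300:], pred, scores, model.classes)
        assert 0.35 <= m["auc"] <= 0.65

    def test_class_mean_assigned_to_its_class(self, rng):
        means = {"a": [0.0, 0.0], "b": [4.0, 0.0], "c": [0.0, 4.0]}
        X, y = _gaussian_classes(rng, means, 50)
        model = fit_ldc(X, y)
        for label, mu in means.items():
            pred, _ = predict_ldc(model, np.array(mu))
            assert pred[0] == label

    def test_minimum_class_size_enforced(self):
        with pytest.raises(ValueError):
            fit_ldc(np.zeros((3, 2)), np.array(["a", "a", "b"]))


class TestRepeatedHoldout:
    def test_stratified_70_30_arithmetic(self):
        y = np.repeat(["a", "b", "c", "d"], 25)
        splits = repeated_holdout(y, n_repeats=5, seed=1)
        for tr, te in splits:
            assert len(te) == 30
            _, counts = np.unique(y[te], return_counts=True)
            assert set(counts) <= {7, 8}

    def test_seed_reproducibility_and_partition(self):
        y = np.repeat(["a", "b"], 20)
        s1 = repeated_holdout(y, n_repeats=3, seed=9)
        s2 = repeated_holdout(y, n_repeats=3, seed=9)
        for (tr1, te1), (tr2, te2) in zip(s1, s2):
            assert np.array_equal(tr1, tr2) and np.array_equal(te1, te2)
            assert len(np.intersect1d(tr1, te1)) == 0
            assert len(np.union1d(tr1, te1)) == len(y)

    def test_tiny_class_rejected(self):
        with pytest.raises(ValueError):
            repeated_holdout(np.array(["a", "a", "b"]))


class TestMetrics:
    def test_known_confusion_counts(self):
        c = {"tp": 8, "fp": 2, "fn": 2, "tn": 88}
        assert acc_from_counts(c) == pytest.approx(0.96)
        assert f1_from_counts(c) == pytest.approx(0.8)

    def test_balanced_confusion(self):
        c = {"tp": 25, "fp": 25, "fn": 25, "tn": 25}
        assert acc_from_counts(c) == 0.5
        assert f1_from_counts(c) == 0.5

    def test_perfect_predictions(self, rng):
        y = np.array(["a", "b"] * 20)
        scores = np.column_stack([(y == "a") * 1.0, (y == "b") * 1.0])
        m = compute_metrics(y, y, scores, np.array(["a", "b"]))
        assert m["acc"] == m["f1"] == m["auc"] == 1.0

    def test_counts_sum_to_test_size(self, rng):
        y = rng.choice(["a", "b", "c"], 60)
        p = rng.choice(["a", "b", "c"], 60)
        conf = confusion_counts(y, p, ["a", "b", "c"])
        for c in conf.values():
            assert c["tp"] + c["tn"] + c["fp"] + c["fn"] == 60

    def test_f1_equals_harmonic_mean_of_precision_recall(self, rng):
        for _ in range(20):
            tp, fp, fn = rng.integers(1, 50, 3)
            c = {"tp": int(tp), "fp": int(fp), "fn": int(fn), "tn": 10}
            prec = tp / (tp + fp)
            rec = tp / (tp + fn)
            assert f1_from_counts(c) == pytest.approx(
                2 * prec * rec / (prec + rec))

    def test_auc_matches_mann_whitney_brute_force(self, rng):
        y = rng.choice(["pos", "neg"], 100)
        s = rng.normal(size=100) + (y == "pos") * 0.8
        scores = np.column_stack([-s, s])  # neg, pos class columns
        m = compute_metrics(y, y, scores, np.array(["neg", "pos"]))
        pos = s[y == "pos"]
        neg = s[y == "neg"]
        brute = np.mean([(p > q) + 0.5 * (p == q) for p in pos for q in neg])
        assert m["auc_per_class"]["pos"] == pytest.approx(brute, abs=1e-12)

    def test_empty_test_set_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(np.array([]), np.array([]), np.zeros((0, 2)),
                            np.array(["a", "b"]))


def _synthetic_featureset(rng, n_per=30, sd=0.3):
    """Separable toy feature set with per-muscle columns (no simulation).

    Each task activates its agonist-antagonist muscles with a distinct
    pattern, and the effort level scales a second per-muscle column of those
    same muscles — so the 2-step scheme's muscle-restricted second stage
    still sees the effort signal.
    """
    efforts = [10.0, 30.0, 50.0]
    muscles = ["brachioradialis", "anconeus", "pronator_teres", "biceps",
               "triceps"]
    activation = {
        "flexion": {"biceps": 3.0, "triceps": 0.5},
        "extension": {"triceps": 3.0, "biceps": 0.5},
        "supination": {"biceps": 2.0, "brachioradialis": 2.0, "anconeus": 1.0},
        "pronation": {"pronator_teres": 3.0, "anconeus": 1.0},
    }
    idx = {m: i for i, m in enumerate(muscles)}
    rows, ts, es = [], [], []
    for t, act in activation.items():
        for e in efforts:
            for _ in range(n_per):
                base = np.zeros(10)
                for m, w in act.items():
                    base[2 * idx[m]] = w
                    base[2 * idx[m] + 1] = w * e / 10.0
                rows.append(base + rng.normal(0, sd, 10))
                ts.append(t)
                es.append(e)
    muscle_cols = {m: [2 * i, 2 * i + 1] for i, m in enumerate(muscles)}
    return FeatureSet(kind="I", X=np.array(rows), tasks=np.array(ts),
                      efforts=np.array(es), muscle_cols=muscle_cols)


class TestEndToEndClassification:
    def test_separable_tasks_identified_almost_perfectly(self, rng):
        fs = _synthetic_featureset(rng)
        res = classify_tasks(fs, n_repeats=10, seed=2)
        assert res.acc_mean >= 0.99
        assert res.auc_mean >= 0.99

    def test_shuffled_labels_fall_to_chance(self, rng):
        fs = _synthetic_featureset(rng)
        fs.tasks = rng.permutation(fs.tasks)
        res = classify_tasks(fs, n_repeats=10, seed=2)
        assert 0.4 <= res.auc_mean <= 0.6

    def test_twelve_composite_classes_enumerated(self, rng):
        fs = _synthetic_featureset(rng)
        res = classify_task_effort(fs, n_repeats=3, seed=2)
        assert len(res.classes) == 12
        assert set(res.classes) == {composite_label(t, e)
                                    for t in TASK_MUSCLES for e in (10, 30, 50)}

    def test_separable_task_effort_identified(self, rng):
        fs = _synthetic_featureset(rng, sd=0.15)
        res = classify_task_effort(fs, n_repeats=5, seed=3)
        assert res.acc_mean >= 0.99

    def test_step1_error_forces_composite_error(self, rng):
        # effort labels shuffled within task: step-2 falls to chance while
        # task routing (and hence task accuracy) is preserved
        fs = _synthetic_featureset(rng)
        for t in np.unique(fs.tasks):
            idx = np.flatnonzero(fs.tasks == t)
            fs.efforts[idx] = rng.permutation(fs.efforts[idx])
        res = classify_task_effort(fs, n_repeats=5, seed=4)
        task_ok = np.mean([np.mean([p.split("_")[0] == tr.split("_")[0]
                                    for p, tr in zip(r["y_pred"], r["y_true"])])
                           for r in res.per_repeat])
        composite_ok = np.mean([np.mean(r["y_pred"] == r["y_true"])
                                for r in res.per_repeat])
        assert task_ok >= 0.99
        assert composite_ok <= 0.55  # ~ 1/3 given correct task


class TestWilcoxonComparison:
    def test_consistent_ordering_is_significant(self):
        a = np.array([0.99, 0.995, 0.992, 0.998, 0.991, 0.996, 0.993, 0.997])
        b = a - 0.004
        out = compare_feature_sets(a, b)
        assert out["p_value"] < 0.05

    def test_identical_sets_not_significant(self):
        a = np.full(10, 0.95)
        out = compare_feature_sets(a, a)
        assert out["p_value"] > 0.5
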