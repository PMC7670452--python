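"""Linear-discriminant identification of task and effort level.

Task identification is a 4-class problem (flexion, extension, supination,
pronation) solved with a linear discriminant classifier (LDC: Gaussian
classes, pooled covariance with Ledoit-Wolf shrinkage). Simultaneous
task+effort identification uses a 2-step scheme: step 1 predicts the task
from the full feature set; step 2 routes the sample to one of four
task-specific effort classifiers (10/30/50 %MVC) restricted to the features
of the agonist-antagonist muscles of that task. Evaluation uses repeated
stratified holdout (70/30, N=20 by default) with per-class accuracy, F1 and
one-vs-rest ROC-AUC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import wilcoxon
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedShuffleSplit

from .features import FeatureSet, pca_apply, pca_reduce, select_muscles

__all__ = ["LdcModel", "EvaluationResult", "fit_ldc", "predict_ldc",
           "repeated_holdout", "compute_metrics", "classify_tasks",
           "classify_task_effort", "TASK_MUSCLES", "compare_feature_sets"]

#: Agonist-antagonist muscle subsets used by the second (effort) step.
TASK_MUSCLES = {
    "flexion": ["biceps", "triceps"],
    "extension": ["biceps", "triceps"],
    "supination": ["biceps", "brachioradialis", "anconeus"],
    "pronation": ["pronator_teres", "anconeus"],
}


@dataclass
class LdcModel:
    """Linear discriminant classifier with pooled shrunk covariance."""
    classes: np.ndarray
    means: np.ndarray       # (n_classes, n_features)
    covariance: np.ndarray  # pooled, after shrinkage
    priors: np.ndarray
    _sk: LinearDiscriminantAnalysis = field(repr=False, default=None)


def fit_ldc(X: np.ndarray, y: np.ndarray, shrinkage="auto") -> LdcModel:
    """Fit the LDC; ``shrinkage`` is 'auto' (Ledoit-Wolf), a float in [0, 1],
    or None (plain pooled covariance, may be singular)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    if counts.min() < 2:
        raise ValueError("every class needs at least 2 training samples")
    lda = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=shrinkage,
                                     store_covariance=True)
    try:
        lda.fit(X, y)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "singular pooled covariance; refit with shrinkage='auto'") from err
    return LdcModel(classes=lda.classes_, means=lda.means_,
                    covariance=lda.covariance_, priors=lda.priors_, _sk=lda)


def predict_ldc(model: LdcModel, X: np.ndarray):
    """Predicted labels and per-class posterior probabilities.

    Posteriors are the ROC score of choice for an LDC: unlike raw
    discriminant values they are comparable across samples, so per-class
    one-vs-rest ranking (AUC) is meaningful. The label is the argmax class;
    ties break deterministically by class order.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    scores = model._sk.predict_proba(X)
    labels = model.classes[np.argmax(scores, axis=1)]
    return labels, scores


def predict_proba_ldc(model: LdcModel, X: np.ndarray) -> np.ndarray:
    return model._sk.predict_proba(np.atleast_2d(np.asarray(X, float)))


def repeated_holdout(labels: np.ndarray, n_repeats: int = 20,
                     train_frac: float = 0.7, seed: int = 0):
    """Seeded per-class stratified train/test splits (70/30 by default)."""
    labels = np.asarray(labels)
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < 2:
        raise ValueError("every class needs >= 2 samples to stratify")
    sss = StratifiedShuffleSplit(n_splits=n_repeats, train_size=train_frac,
                                 random_state=seed)
    return [(tr, te) for tr, te in sss.split(np.zeros(len(labels)), labels)]


@dataclass
class EvaluationResult:
    """Per-repeat predictions and metrics plus their mean +- sd aggregates."""
    classes: np.ndarray
    per_repeat: list  # dicts: test_idx, y_true, y_pred, confusions, acc, f1, auc
    acc_mean: float
    acc_sd: float
    f1_mean: float
    f1_sd: float
    auc_mean: float
    auc_sd: float

    @classmethod
    def from_repeats(cls, classes, per_repeat):
        acc = np.array([r["acc"] for r in per_repeat])
        f1 = np.array([r["f1"] for r in per_repeat])
        auc = np.array([r["auc"] for r in per_repeat])
        return cls(classes=np.asarray(classes), per_repeat=per_repeat,
                   acc_mean=float(acc.mean()), acc_sd=float(acc.std(ddof=0)),
                   f1_mean=float(f1.mean()), f1_sd=float(f1.std(ddof=0)),
                   auc_mean=float(auc.mean()), auc_sd=float(auc.std(ddof=0)))


def confusion_counts(y_true, y_pred, classes) -> dict:
    """Per-class one-vs-rest TP/TN/FP/FN counts."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    out = {}
    for c in classes:
        t = y_true == c
        p = y_pred == c
        out[c] = {"tp": int(np.sum(t & p)), "tn": int(np.sum(~t & ~p)),
                  "fp": int(np.sum(~t & p)), "fn": int(np.sum(t & ~p))}
    return out


def acc_from_counts(c: dict) -> float:
    return (c["tp"] + c["tn"]) / max(c["tp"] + c["tn"] + c["fp"] + c["fn"], 1)


def f1_from_counts(c: dict) -> float:
    denom = 2 * c["tp"] + c["fp"] + c["fn"]
    return 2 * c["tp"] / denom if denom else 1.0


def compute_metrics(y_true, y_pred, scores, classes) -> dict:
    """Per-class ACC = (TP+TN)/(TP+TN+FP+FN) and F1 = 2TP/(2TP+FP+FN), plus
    one-vs-rest AUC from the class scores; macro-averaged aggregates."""
    y_true = np.asarray(y_true)
    if y_true.size == 0:
        raise ValueError("empty test set")
    classes = np.asarray(classes)
    conf = confusion_counts(y_true, y_pred, classes)
    accs = {c: acc_from_counts(conf[c]) for c in classes}
    f1s = {c: f1_from_counts(conf[c]) for c in classes}
    aucs = {}
    for j, c in enumerate(classes):
        t = (y_true == c).astype(int)
        if t.min() == t.max():  # class absent (or alone) in the test set
            aucs[c] = np.nan
            continue
        aucs[c] = float(roc_auc_score(t, np.asarray(scores)[:, j]))
    macro_auc = float(np.nanmean(list(aucs.values())))
    return {"confusions": conf, "acc_per_class": accs, "f1_per_class": f1s,
            "auc_per_class": aucs,
            "acc": float(np.mean(list(accs.values()))),
            "f1": float(np.mean(list(f1s.values()))),
            "auc": macro_auc}


def _prepare_split(fs: FeatureSet, train_idx, pca_threshold=0.90):
    """Per-split design matrices: PCA (fit on train only) applied to the
    feature set's designated block, passthrough columns untouched."""
    X = fs.X
    if fs.pca_cols.size:
        keep = np.setdiff1d(np.arange(X.shape[1]), fs.pca_cols)
        model = pca_reduce(X[np.ix_(train_idx, fs.pca_cols)],
                           threshold=pca_threshold)
        reduced = pca_apply(model, X[:, fs.pca_cols])
        return np.hstack([X[:, keep], reduced])
    return X


def classify_tasks(fs: FeatureSet, splits=None, *, n_repeats: int = 20,
                   seed: int = 0, shrinkage="auto",
                   pca_threshold: float = 0.90) -> EvaluationResult:
    """Task identification over all recordings regardless of effort level."""
    y = fs.tasks
    if splits is None:
        splits = repeated_holdout(y, n_repeats=n_repeats, seed=seed)
    classes = np.unique(y)
    per_repeat = []
    for tr, te in splits:
        Xall = _prepare_split(fs, tr, pca_threshold)
        model = fit_ldc(Xall[tr], y[tr], shrinkage=shrinkage)
        unseen = set(y[te]) - set(model.classes)
        if unseen:
            raise ValueError(f"labels {unseen} unseen during training")
        y_pred, scores = predict_ldc(model, Xall[te])
        m = compute_metrics(y[te], y_pred, scores, model.classes)
        m.update(test_idx=te, y_true=y[te], y_pred=y_pred)
        per_repeat.append(m)
    return EvaluationResult.from_repeats(classes, per_repeat)


def composite_label(task, effort) -> str:
    return f"{task}_{int(effort)}"


def classify_task_effort(fs: FeatureSet, splits=None, *, n_repeats: int = 20,
                         seed: int = 0, shrinkage="auto",
                         pca_threshold: float = 0.90) -> EvaluationResult:
    """2-step identification of the 12 composite task+effort classes.

    Step-2 classifiers are trained on the true task partitions of the
    training split, each restricted to its task's muscle-feature blocks; at
    prediction time the step-1 task decision routes the sample, so a step-1
    error makes the composite prediction wrong by construction.
    """
    tasks = fs.tasks
    efforts = fs.efforts
    y_comp = np.array([composite_label(t, e) for t, e in zip(tasks, efforts)])
    if splits is None:
        splits = repeated_holdout(y_comp, n_repeats=n_repeats, seed=seed)
    task_names = list(TASK_MUSCLES)
    effort_levels = np.unique(efforts)
    classes = np.array([composite_label(t, e)
                        for t in sorted(np.unique(tasks).tolist())
                        for e in effort_levels])
    sub_sets = {t: select_muscles(fs, TASK_MUSCLES[t]) for t in task_names
                if t in set(tasks)}
    per_repeat = []
    for tr, te in splits:
        X1 = _prepare_split(fs, tr, pca_threshold)
        step1 = fit_ldc(X1[tr], tasks[tr], shrinkage=shrinkage)
        step2 = {}
        X2 = {}
        for t, sub in sub_sets.items():
            X2[t] = _prepare_split(sub, tr, pca_threshold)
            mask = tasks[tr] == t
            step2[t] = fit_ldc(X2[t][tr][mask], efforts[tr][mask],
                               shrinkage=shrinkage)
        task_pred, _ = predict_ldc(step1, X1[te])
        p_task = predict_proba_ldc(step1, X1[te])
        y_pred = np.empty(len(te), dtype=object)
        scores = np.zeros((len(te), len(classes)))
        class_pos = {c: j for j, c in enumerate(classes)}
        for i, (idx, t_hat) in enumerate(zip(te, task_pred)):
            m2 = step2[t_hat]
            eff_pred, _ = predict_ldc(m2, X2[t_hat][idx])
            y_pred[i] = composite_label(t_hat, eff_pred[0])
            # composite score: P(task) * P(effort | task's classifier)
            for jt, t in enumerate(step1.classes):
                p2 = predict_proba_ldc(step2[t], X2[t][idx])[0]
                for je, e in enumerate(step2[t].classes):
                    scores[i, class_pos[composite_label(t, e)]] = \
                        p_task[i, jt] * p2[je]
        y_pred = y_pred.astype(str)
        m = compute_metrics(y_comp[te], y_pred, scores, classes)
        m.update(test_idx=te, y_true=y_comp[te], y_pred=y_pred,
                 task_pred=task_pred)
        per_repeat.append(m)
    return EvaluationResult.from_repeats(classes, per_repeat)


def compare_feature_sets(auc_a: np.ndarray, auc_b: np.ndarray) -> dict:
    """Paired Wilcoxon signed-rank comparison of two feature sets' AUCs
    (paired over subjects or seeds). Returns the one-sided p-value for
    'a greater than b' alongside means."""
    auc_a = np.asarray(auc_a, float)
    auc_b = np.asarray(auc_b, float)
    if auc_a.shape != auc_b.shape:
        raise ValueError("paired samples must have equal length")
    diff = auc_a - auc_b
    if np.allclose(diff, 0):
        stat, p = 0.0, 1.0
    else:
        stat, p = wilcoxon(auc_a, auc_b, alternative="greater",
                           zero_method="wilcox")
    return {"mean_a": float(auc_a.mean()), "mean_b": float(auc_b.mean()),
            "statistic": float(stat), "p_value": float(p)}
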