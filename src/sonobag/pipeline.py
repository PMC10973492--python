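"""Balanced splitting, training wrappers, metrics and repeated runs.

The cohort is heavily imbalanced (the normal class dominates), so
splits first down-sample every class to the size of the rarest one and
then apportion that common size n_min to train/validation/test in fixed
proportions (81/9/10) by floor-then-largest-remainder, which makes the
three partition sizes sum exactly to n_min. Metrics follow the printed
definitions: accuracy, per-class precision TP/(TP+FP), recall
TP/(TP+FN) and f1 = TP/(TP + 0.5(FP+FN)); classes with an undefined
ratio report 0 with a warning. Repeated experiments re-split and
retrain with derived seeds and report mean ± standard error (sd/√n).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import auc, roc_curve

from .estimators import GroupGraphClassifier

__all__ = [
    "SplitSpec",
    "ClassSplit",
    "ConfusionCounts",
    "balanced_split",
    "train_model",
    "evaluate_classifier",
    "roc_auc",
    "repeat_experiments",
]

DEFAULT_PROPORTIONS = (0.81, 0.09, 0.10)


@dataclass
class SplitSpec:
    proportions: tuple[float, float, float] = DEFAULT_PROPORTIONS
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.proportions) - 1.0) > 1e-9:
            raise ValueError("proportions must sum to 1")


@dataclass
class ClassSplit:
    """Per-class index sets into that class's own subject list."""

    train: np.ndarray
    val: np.ndarray
    test: np.ndarray


@dataclass
class ConfusionCounts:
    matrix: np.ndarray  # rows = true class, cols = predicted class
    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray


@dataclass
class EvalResult:
    accuracy: float
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    confusion: ConfusionCounts


def apportion(n: int, proportions=DEFAULT_PROPORTIONS) -> tuple[int, ...]:
    """Floor + largest-remainder apportionment of n to the proportions."""
    quotas = np.asarray(proportions) * n
    base = np.floor(quotas).astype(int)
    rem = quotas - base
    short = n - base.sum()
    # hand leftover units to the largest remainders; ties to the earlier slot
    for idx in np.argsort(-rem, kind="stable")[:short]:
        base[idx] += 1
    return tuple(int(b) for b in base)


def balanced_split(class_counts: dict | list, spec: SplitSpec | None = None) -> dict:
    """Down-sample every class to n_min, then split 81/9/10.

    `class_counts` maps class label -> subject count (or is a list of
    counts, keyed 0..K-1). Returns {label: ClassSplit} where the index
    arrays index into the class's own subjects; the union of the three
    sets is a random n_min-subset of the class, drawn without
    replacement with the spec's seed.
    """
    spec = spec or SplitSpec()
    if not isinstance(class_counts, dict):
        class_counts = dict(enumerate(class_counts))
    counts = np.array(list(class_counts.values()))
    if np.any(counts < 3):
        raise ValueError("every class needs >= 3 subjects to fill three partitions")
    n_min = int(counts.min())
    n_tr, n_va, n_te = apportion(n_min, spec.proportions)
    if min(n_tr, n_va, n_te) == 0:
        warnings.warn("a partition is empty at this pool size", UserWarning, stacklevel=2)
    rng = np.random.default_rng(spec.seed)
    out = {}
    for label, count in class_counts.items():
        pool = rng.permutation(count)[:n_min]
        out[label] = ClassSplit(
            train=np.sort(pool[:n_tr]),
            val=np.sort(pool[n_tr:n_tr + n_va]),
            test=np.sort(pool[n_tr + n_va:]),
        )
    return out


def train_model(features: list, labels, kind: str = "gat", n_blocks: int = 1,
                hidden_dim: int = 512, epochs: int = 100, batch_size: int = 32,
                base_lr: float = 1e-3, tau: float = 0.995, seed: int = 0,
                val_features: list | None = None, val_labels=None,
                **kwargs) -> GroupGraphClassifier:
    """Fit a :class:`GroupGraphClassifier` on frozen features.

    Thin functional wrapper; the returned estimator carries the
    per-epoch training loss in ``loss_trace_`` and, when a validation
    set is given, the per-epoch-end validation loss in ``val_trace_``.
    """
    clf = GroupGraphClassifier(kind=kind, n_blocks=n_blocks, hidden_dim=hidden_dim,
                               epochs=epochs, batch_size=batch_size, base_lr=base_lr,
                               tau=tau, seed=seed, **kwargs)
    clf.fit(features, labels)
    if val_features is not None:
        proba = clf.predict_proba(val_features)
        y_idx = np.searchsorted(clf.classes_, np.asarray(val_labels))
        nll = -np.log(np.maximum(proba[np.arange(len(val_features)), y_idx], 1e-300))
        clf.val_trace_ = [float(nll.mean())]
    return clf


def evaluate_classifier(predictions, labels, classes=None) -> EvalResult:
    """Accuracy plus per-class precision/recall/f1 from the confusion
    matrix (rows true, columns predicted)."""
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    if predictions.size != labels.size or labels.size == 0:
        raise ValueError("predictions and labels must be equal-length and nonempty")
    if classes is None:
        classes = np.unique(np.concatenate([labels, predictions]))
    classes = np.asarray(classes)
    K = classes.size
    lut = {c: i for i, c in enumerate(classes)}
    M = np.zeros((K, K), dtype=int)
    for t, p in zip(labels, predictions):
        M[lut[t], lut[p]] += 1
    tp = np.diag(M).astype(float)
    fp = M.sum(axis=0) - tp
    fn = M.sum(axis=1) - tp

    def _safe(num, den, name):
        out = np.zeros(K)
        for k in range(K):
            if den[k] == 0:
                warnings.warn(f"{name} undefined for class {classes[k]}; reporting 0",
                              UserWarning, stacklevel=3)
            else:
                out[k] = num[k] / den[k]
        return out

    precision = _safe(tp, tp + fp, "precision")
    recall = _safe(tp, tp + fn, "recall")
    f1 = _safe(tp, tp + 0.5 * (fp + fn), "f1")
    return EvalResult(
        accuracy=float(tp.sum() / M.sum()),
        precision=precision,
        recall=recall,
        f1=f1,
        confusion=ConfusionCounts(matrix=M, tp=tp.astype(int), fp=fp.astype(int),
                                  fn=fn.astype(int)),
    )


def roc_auc(proba: np.ndarray, labels, classes=None) -> dict:
    """One-vs-rest ROC curve and trapezoidal AUC per class.

    `proba` is (n, K) with columns ordered like `classes` (defaults to
    the sorted unique labels)."""
    proba = np.asarray(proba, dtype=float)
    labels = np.asarray(labels)
    if classes is None:
        classes = np.unique(labels)
    classes = np.asarray(classes)
    if classes.size < 2:
        raise ValueError("need at least two distinct classes")
    out = {}
    for k, c in enumerate(classes):
        y_bin = (labels == c).astype(int)
        fpr, tpr, _ = roc_curve(y_bin, proba[:, k])
        out[c] = {"fpr": fpr, "tpr": tpr, "auc": float(auc(fpr, tpr))}
    return out


@dataclass
class RepeatResult:
    metrics: dict  # name -> (mean, se)
    per_rep: dict = field(repr=False, default_factory=dict)


def repeat_experiments(features: list, labels, n_reps: int = 10, seed: int = 0,
                       train_frac_spec: SplitSpec | None = None,
                       **train_kwargs) -> RepeatResult:
    """Repeat balanced split -> train -> test `n_reps` times.

    Each repetition uses a derived seed for the split and the training;
    reports mean and standard error (sd/√n) of accuracy and the
    macro-averaged precision/recall/f1 on the test partition.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    labels = np.asarray(labels)
    classes = np.unique(labels)
    by_class = {c: np.nonzero(labels == c)[0] for c in classes}
    per_rep: dict[str, list[float]] = {
        "accuracy": [], "precision": [], "recall": [], "f1": []}
    for rep in range(n_reps):
        rep_seed = seed + rep
        split = balanced_split({c: idx.size for c, idx in by_class.items()},
                               SplitSpec(seed=rep_seed))
        tr_idx = np.concatenate([by_class[c][split[c].train] for c in classes])
        te_idx = np.concatenate([by_class[c][split[c].test] for c in classes])
        clf = train_model([features[i] for i in tr_idx], labels[tr_idx],
                          seed=rep_seed, **train_kwargs)
        pred = clf.predict([features[i] for i in te_idx])
        res = evaluate_classifier(pred, labels[te_idx], classes=classes)
        per_rep["accuracy"].append(res.accuracy)
        per_rep["precision"].append(float(res.precision.mean()))
        per_rep["recall"].append(float(res.recall.mean()))
        per_rep["f1"].append(float(res.f1.mean()))
    metrics = {}
    for name, vals in per_rep.items():
        arr = np.asarray(vals)
        metrics[name] = (float(arr.mean()), float(arr.std(ddof=1) / np.sqrt(n_reps)))
    return RepeatResult(metrics=metrics, per_rep=per_rep)
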