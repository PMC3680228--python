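"""Evaluation protocol: repeated random sub-sampling and k-fold CV.

The reference protocol draws 100 training and 30 test points at random
(stratified), repeats ten times, and reports per-class accuracy
(one-vs-rest recall), sensitivity and specificity as mean ± SD in
percent.  A stratified ten-fold cross-validation mode is also provided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import StratifiedKFold

from .tsvm import predict_multiclass, train_multiclass

__all__ = [
    "ConfusionMatrix",
    "EvaluationReport",
    "random_subsample_split",
    "cross_validate",
    "confusion_metrics",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts with rows = true class, columns = predicted class."""

    counts: np.ndarray
    class_names: list[str]

    def __post_init__(self):
        c = np.asarray(self.counts, dtype=int)
        if c.ndim != 2 or c.shape[0] != c.shape[1] or np.any(c < 0):
            raise ValueError("confusion matrix must be square and non-negative")
        object.__setattr__(self, "counts", c)

    @classmethod
    def from_labels(cls, y_true, y_pred, class_names) -> "ConfusionMatrix":
        counts = _sk_confusion(y_true, y_pred, labels=list(class_names))
        return cls(counts=counts, class_names=list(class_names))

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def confusion_metrics(cm: ConfusionMatrix, class_k: int) -> tuple[float, float]:
    """One-vs-rest (sensitivity, specificity) in percent for class ``class_k``.

    Sensitivity = TP/(TP+FN), specificity = TN/(TN+FP).  If the class is
    absent from the test set (or no negatives exist) the corresponding
    rate is undefined and returned as NaN with a warning.
    """
    c = cm.counts
    tp = c[class_k, class_k]
    fn = c[class_k].sum() - tp
    fp = c[:, class_k].sum() - tp
    tn = c.sum() - tp - fn - fp
    if tp + fn == 0:
        warnings.warn(f"class {cm.class_names[class_k]} absent from the test set; "
                      "sensitivity undefined", stacklevel=2)
        sens = float("nan")
    else:
        sens = 100.0 * tp / (tp + fn)
    if tn + fp == 0:
        warnings.warn(f"no negatives for class {cm.class_names[class_k]}; "
                      "specificity undefined", stacklevel=2)
        spec = float("nan")
    else:
        spec = 100.0 * tn / (tn + fp)
    return sens, spec


@dataclass
class EvaluationReport:
    """Mean ± SD rates (percent) over repetitions or folds."""

    class_names: list[str]
    per_class_accuracy: dict[str, tuple[float, float]]
    per_class_sensitivity: dict[str, tuple[float, float]]
    per_class_specificity: dict[str, tuple[float, float]]
    overall_accuracy: tuple[float, float]
    n_repetitions: int
    seed: int
    mode: str
    pooled_confusion: ConfusionMatrix | None = None

    def to_dict(self) -> dict:
        def pairs(d):
            return {k: {"mean": v[0], "sd": v[1]} for k, v in d.items()}
        out = {
            "mode": self.mode,
            "seed": self.seed,
            "n_repetitions": self.n_repetitions,
            "class_names": list(self.class_names),
            "per_class_accuracy": pairs(self.per_class_accuracy),
            "per_class_sensitivity": pairs(self.per_class_sensitivity),
            "per_class_specificity": pairs(self.per_class_specificity),
            "overall_accuracy": {"mean": self.overall_accuracy[0],
                                 "sd": self.overall_accuracy[1]},
        }
        if self.pooled_confusion is not None:
            out["pooled_confusion"] = self.pooled_confusion.counts.tolist()
        return out


def _stratified_counts(n_total: int, class_names, rule: str = "lower-first") -> dict:
    """Split n_total as evenly as possible; remainder to lower class indices."""
    k = len(class_names)
    base, rem = divmod(n_total, k)
    return {name: base + (1 if i < rem else 0) for i, name in enumerate(class_names)}


def random_subsample_split(X, y, n_train: int = 100, n_test: int = 30,
                           seed: int = 0, class_names: list[str] | None = None):
    """Disjoint stratified train/test subsample (the 100/30 protocol).

    Per-class quotas are as even as integer division allows, with the
    remainder given to lower class indices.  Reproducible for a fixed
    seed; train and test never share a point.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray([str(v) for v in y])
    if class_names is None:
        class_names = sorted(set(y))
    train_quota = _stratified_counts(n_train, class_names)
    test_quota = _stratified_counts(n_test, class_names)
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for name in class_names:
        idx = np.flatnonzero(y == name)
        need = train_quota[name] + test_quota[name]
        if len(idx) < need:
            raise ValueError(
                f"class {name} has {len(idx)} points; needs >= {need} "
                f"for a {n_train}/{n_test} split"
            )
        perm = rng.permutation(idx)
        train_idx.extend(perm[: train_quota[name]])
        test_idx.extend(perm[train_quota[name]: need])
    train_idx = np.asarray(sorted(train_idx))
    test_idx = np.asarray(sorted(test_idx))
    return (X[train_idx], y[train_idx]), (X[test_idx], y[test_idx])


def _rates_for(y_true, y_pred, class_names):
    cm = ConfusionMatrix.from_labels(y_true, y_pred, class_names)
    acc, sens, spec = {}, {}, {}
    for i, name in enumerate(class_names):
        s, p = confusion_metrics(cm, i)
        sens[name] = s
        spec[name] = p
        acc[name] = s  # per-class accuracy = one-vs-rest recall
    overall = 100.0 * np.mean(np.asarray(y_true) == np.asarray(y_pred))
    return cm, acc, sens, spec, overall


def _mean_sd(values) -> tuple[float, float]:
    v = np.asarray(values, dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return float(np.nanmean(v)), float(np.nanstd(v, ddof=1)) if len(v) > 1 else 0.0


def cross_validate(X, y, mode: str = "subsample", n_repetitions: int = 10,
                   n_train: int = 100, n_test: int = 30, n_folds: int = 10,
                   seed: int = 0, c1: float = 1.0, c2: float = 1.0,
                   eps: float = 1e-6,
                   class_names: list[str] | None = None) -> EvaluationReport:
    """Train/evaluate the TSVM under the chosen protocol.

    ``subsample``: ``n_repetitions`` independent stratified 100/30
    random splits.  ``kfold``: stratified ``n_folds``-fold CV.  Rates
    are aggregated as mean ± SD across repetitions/folds.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray([str(v) for v in y])
    if class_names is None:
        class_names = sorted(set(y))

    splits = []
    if mode == "subsample":
        for r in range(n_repetitions):
            splits.append(random_subsample_split(
                X, y, n_train=n_train, n_test=n_test,
                seed=(seed + 7919 * r) % 2**31, class_names=class_names))
    elif mode == "kfold":
        counts = {name: int(np.sum(y == name)) for name in class_names}
        bad = [n for n, c in counts.items() if c < n_folds]
        if bad:
            raise ValueError(
                f"classes {bad} have fewer than {n_folds} samples; "
                "use fewer folds"
            )
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed % 2**31)
        for tr, te in skf.split(X, y):
            splits.append(((X[tr], y[tr]), (X[te], y[te])))
    else:
        raise ValueError(f"unknown evaluation mode {mode!r}")

    accs, senss, specs, overalls = [], [], [], []
    pooled = np.zeros((len(class_names), len(class_names)), dtype=int)
    for (X_tr, y_tr), (X_te, y_te) in splits:
        model = train_multiclass(X_tr, y_tr, c1=c1, c2=c2, eps=eps,
                                 class_names=class_names)
        y_hat, _ = predict_multiclass(model, X_te)
        cm, acc, sens, spec, overall = _rates_for(y_te, y_hat, class_names)
        pooled += cm.counts
        accs.append(acc)
        senss.append(sens)
        specs.append(spec)
        overalls.append(overall)

    def collect(dicts):
        return {name: _mean_sd([d[name] for d in dicts]) for name in class_names}

    return EvaluationReport(
        class_names=list(class_names),
        per_class_accuracy=collect(accs),
        per_class_sensitivity=collect(senss),
        per_class_specificity=collect(specs),
        overall_accuracy=_mean_sd(overalls),
        n_repetitions=len(splits),
        seed=seed,
        mode=mode,
        pooled_confusion=ConfusionMatrix(pooled, list(class_names)),
    )
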