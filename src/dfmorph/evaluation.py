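"""Repeated stratified K-fold cross-validation and the four evaluation indicators.

A correctly detected AD subject (label 1) counts as a true positive.  Per CV
repetition the cohort is split into K mutually exclusive folds of nearly equal
size (stratified by default — with only ~1 AD per 3.5 NC, unstratified folds
frequently contain no AD subject at all); each fold's validation predictions
are assembled into one full-cohort out-of-fold prediction vector, giving one
confusion table and one set of metrics per repetition.  Results are reported
as mean +- SD over repetitions.  Inside every fold the PCA and the classifier
see training rows only.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold

from . import classifiers as clf
from .features import fit_pca, transform

__all__ = ["ConfusionCounts", "Metrics", "EvalReport", "metrics",
           "stratified_folds", "run_cv", "CLASSIFIERS"]

METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "precision")


@dataclass
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass
class Metrics:
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in METRIC_NAMES}


def metrics(c: ConfusionCounts) -> Metrics:
    """Accuracy, sensitivity (recall), specificity and precision of a
    confusion table; ratios with a zero denominator come back as NaN with a
    warning."""
    if c.total == 0:
        raise ValueError("empty confusion table")

    def ratio(num, den, name):
        if den == 0:
            warnings.warn(f"{name} undefined (zero denominator); reporting NaN")
            return float("nan")
        return num / den

    return Metrics(
        accuracy=(c.TN + c.TP) / c.total,
        sensitivity=ratio(c.TP, c.FN + c.TP, "sensitivity"),
        specificity=ratio(c.TN, c.FP + c.TN, "specificity"),
        precision=ratio(c.TP, c.TP + c.FP, "precision"),
    )


def confusion_from_predictions(y_true, y_pred, positive=1) -> ConfusionCounts:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    pos = y_true == positive
    return ConfusionCounts(
        TP=int(np.sum(pos & (y_pred == positive))),
        FN=int(np.sum(pos & (y_pred != positive))),
        TN=int(np.sum(~pos & (y_pred != positive))),
        FP=int(np.sum(~pos & (y_pred == positive))),
    )


def stratified_folds(y, K: int = 10, seed: int = 0, stratify: bool = True) -> np.ndarray:
    """Fold assignment (values 0..K-1) for every sample.

    Stratified folds keep per-class counts per fold within one of each other;
    fold sizes differ by at most one.  Deterministic given ``seed``.  A class
    with fewer than K members triggers a best-effort warning (folds then may
    miss that class).
    """
    y = np.asarray(y)
    n = y.size
    if n < K:
        raise ValueError(f"need at least K={K} samples, got {n}")
    if np.unique(y).size < 2:
        raise ValueError("both classes must be present")
    assignment = np.empty(n, dtype=int)
    if stratify:
        counts = np.bincount(y.astype(int))
        if counts[counts > 0].min() < K:
            warnings.warn(
                f"a class has fewer than K={K} members; stratification is best-effort")
            splitter = KFold(n_splits=K, shuffle=True, random_state=seed)
            splits = splitter.split(y)
        else:
            splitter = StratifiedKFold(n_splits=K, shuffle=True, random_state=seed)
            splits = splitter.split(np.zeros((n, 1)), y)
    else:
        splitter = KFold(n_splits=K, shuffle=True, random_state=seed)
        splits = splitter.split(y)
    for fold, (_, val_idx) in enumerate(splits):
        assignment[val_idx] = fold
    return assignment


@dataclass
class EvalReport:
    """Per-repetition metrics and their mean +- SD."""

    classifier: str
    K: int
    repeats: int
    seed: int
    per_repetition: dict = field(default_factory=dict)  # metric -> list of floats
    confusions: list = field(default_factory=list)      # one ConfusionCounts per repetition

    @property
    def mean(self) -> dict:
        return {m: float(np.mean(v)) for m, v in self.per_repetition.items()}

    @property
    def sd(self) -> dict:
        return {m: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
                for m, v in self.per_repetition.items()}

    def summary(self) -> dict:
        return {m: {"mean": self.mean[m], "sd": self.sd[m]} for m in METRIC_NAMES}

    def to_json(self, path=None) -> str:
        payload = {
            "classifier": self.classifier, "K": self.K, "repeats": self.repeats,
            "seed": self.seed, "summary": self.summary(),
            "per_repetition": self.per_repetition,
            "confusions": [vars(c) for c in self.confusions],
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _fit_predict(name, params, X_train, y_train, X_val, positive=1):
    """Fit one classifier on training rows and predict validation rows."""
    params = dict(params or {})
    X1 = X_train[y_train == positive]
    X2 = X_train[y_train != positive]
    neg = int(np.unique(y_train[y_train != positive])[0]) if np.any(y_train != positive) else 0
    labels = (positive, neg)
    if name == "svm":
        model = clf.fit_linear_svm(X1, X2, C=params.get("C", 1.0), labels=labels)
        return clf.predict_linear_svm(model, X_val)
    if name == "gepsvm":
        model = clf.fit_gepsvm(X1, X2, t=params.get("t", 1e-4), labels=labels)
        return clf.predict_gepsvm(model, X_val)
    if name == "tsvm":
        model = clf.fit_tsvm(X1, X2, c1=params.get("c1", 1.0),
                             c2=params.get("c2", 1.0), labels=labels)
        return clf.predict_tsvm(model, X_val)
    raise ValueError(f"unknown classifier {name!r}; expected svm, gepsvm or tsvm")


CLASSIFIERS = ("svm", "gepsvm", "tsvm")


def run_cv(X, y, classifier_spec, K: int = 10, repeats: int = 50, seed: int = 0,
           variance_fraction: float | None = 0.95, stratify: bool = True,
           positive: int = 1) -> EvalReport:
    """Repeated stratified K-fold CV with out-of-fold assembly.

    ``classifier_spec`` is a name in {"svm", "gepsvm", "tsvm"} or a dict
    ``{"name": ..., "params": {...}}``.  Per repetition a fresh stratified
    split (seeded ``seed + repetition``) is drawn; per fold a PCA (when
    ``variance_fraction`` is not None) and the classifier are fitted on
    training rows only and validation rows are predicted; the out-of-fold
    predictions form one confusion table per repetition.  The report carries
    per-repetition metrics and their mean +- SD.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.shape[0] != y.size:
        raise ValueError("X rows must align with y")
    if isinstance(classifier_spec, str):
        name, params = classifier_spec, {}
    else:
        name, params = classifier_spec["name"], classifier_spec.get("params", {})
    if name not in CLASSIFIERS:
        raise ValueError(f"unknown classifier {name!r}")

    report = EvalReport(classifier=name, K=K, repeats=repeats, seed=seed,
                        per_repetition={m: [] for m in METRIC_NAMES})
    for rep in range(repeats):
        folds = stratified_folds(y, K=K, seed=seed + rep, stratify=stratify)
        y_pred = np.full(y.size, -999, dtype=int)
        for fold in range(K):
            val = folds == fold
            train = ~val
            try:
                X_train, X_val = X[train], X[val]
                if variance_fraction is not None:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        pca = fit_pca(X_train, variance_fraction)
                    X_train = transform(pca, X_train)
                    X_val = transform(pca, X_val)
                y_pred[val] = _fit_predict(name, params, X_train, y[train], X_val,
                                           positive=positive)
            except Exception as exc:
                raise RuntimeError(
                    f"classifier fit failed at repetition {rep}, fold {fold}") from exc
        assert np.all(y_pred != -999), "out-of-fold assembly left unpredicted rows"
        conf = confusion_from_predictions(y, y_pred, positive=positive)
        report.confusions.append(conf)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = metrics(conf)
        for k in METRIC_NAMES:
            report.per_repetition[k].append(getattr(m, k))
    return report
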