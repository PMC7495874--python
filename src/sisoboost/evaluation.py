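"""Confusion-matrix metrics, ROC/AUC, and the repeated stratified
cross-validation harness with leakage-safe per-fold embedding."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold, KFold

from .classifier import BoostParams, fit_classifier, predict_proba
from .manifold import (
    FeatureTable,
    SISOMAPParams,
    sisomap_fit,
    sisomap_fit_transductive,
    sisomap_transform,
)


@dataclass
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        for name in ("TP", "FP", "TN", "FN"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"{name} must be a non-negative integer")
            setattr(self, name, int(v))

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass
class MetricsReport:
    SEN: float
    SPE: float
    PRE: float
    F1: float
    ACC: float
    MCC: float
    counts: ConfusionCounts
    AUC: Optional[float] = None

    def as_dict(self) -> dict:
        out = {
            "SEN": self.SEN,
            "SPE": self.SPE,
            "PRE": self.PRE,
            "F1": self.F1,
            "ACC": self.ACC,
            "MCC": self.MCC,
            "TP": self.counts.TP,
            "FP": self.counts.FP,
            "TN": self.counts.TN,
            "FN": self.counts.FN,
        }
        if self.AUC is not None:
            out["AUC"] = self.AUC
        return out


@dataclass
class CVConfig:
    folds: int = 10
    repeats: int = 20
    base_seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


@dataclass
class CVResult:
    mean: dict
    std: dict
    per_repeat: list = field(default_factory=list)


def confusion_from_predictions(y_true, y_pred) -> ConfusionCounts:
    """Exact TP/FP/TN/FN counts; positive class is label 1."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if y_true.size and not (
        np.isin(y_true, (0, 1)).all() and np.isin(y_pred, (0, 1)).all()
    ):
        raise ValueError("labels must be binary 0/1")
    y_true = y_true.astype(int)
    y_pred = y_pred.astype(int)
    return ConfusionCounts(
        TP=int(((y_true == 1) & (y_pred == 1)).sum()),
        FP=int(((y_true == 0) & (y_pred == 1)).sum()),
        TN=int(((y_true == 0) & (y_pred == 0)).sum()),
        FN=int(((y_true == 1) & (y_pred == 0)).sum()),
    )


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"zero denominator in {what}; reporting 0", stacklevel=3)
        return 0.0
    return num / den


def compute_metrics(c: ConfusionCounts) -> MetricsReport:
    """Sensitivity, specificity, precision, F1, accuracy and MCC from
    counts.  Zero denominators yield 0 with a warning."""
    if c.total == 0:
        raise ValueError("cannot compute metrics on zero samples")
    sen = _safe_div(c.TP, c.TP + c.FN, "SEN")
    spe = _safe_div(c.TN, c.TN + c.FP, "SPE")
    pre = _safe_div(c.TP, c.TP + c.FP, "PRE")
    f1 = _safe_div(2 * sen * pre, sen + pre, "F1")
    acc = (c.TP + c.TN) / c.total
    mcc_den = np.sqrt(
        float(c.TP + c.FP) * (c.TP + c.FN) * (c.TN + c.FP) * (c.TN + c.FN)
    )
    mcc = _safe_div(c.TP * c.TN - c.FP * c.FN, mcc_den, "MCC")
    return MetricsReport(SEN=float(sen), SPE=float(spe), PRE=float(pre),
                         F1=float(f1), ACC=float(acc), MCC=float(mcc),
                         counts=c)


def roc_auc(y_true, scores) -> float:
    """AUC as the Mann-Whitney probability that a random positive outscores
    a random negative, ties counted half."""
    y_true = np.asarray(y_true).astype(int)
    scores = np.asarray(scores, dtype=float)
    if y_true.shape != scores.shape:
        raise ValueError("y_true and scores must have equal length")
    n_pos = int((y_true == 1).sum())
    n_neg = int((y_true == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes present")
    ranks = rankdata(scores)  # average ranks handle ties as half credit
    rank_sum = ranks[y_true == 1].sum()
    return float((rank_sum - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def roc_curve_points(y_true, scores) -> tuple[np.ndarray, np.ndarray]:
    """(FPR, TPR) coordinates at every distinct threshold, for trapezoidal
    integration and for writing ROC CSVs."""
    y_true = np.asarray(y_true).astype(int)
    scores = np.asarray(scores, dtype=float)
    order = np.argsort(-scores, kind="stable")
    y_sorted = y_true[order]
    s_sorted = scores[order]
    tps = np.cumsum(y_sorted == 1)
    fps = np.cumsum(y_sorted == 0)
    # keep only the last index of each tied score block
    distinct = np.r_[np.nonzero(np.diff(s_sorted))[0], y_sorted.size - 1]
    tps, fps = tps[distinct], fps[distinct]
    n_pos, n_neg = tps[-1], fps[-1]
    tpr = np.r_[0.0, tps / n_pos] if n_pos else np.r_[0.0, np.zeros(len(tps))]
    fpr = np.r_[0.0, fps / n_neg] if n_neg else np.r_[0.0, np.zeros(len(fps))]
    return fpr, tpr


def roc_auc_trapezoid(y_true, scores) -> float:
    """AUC by trapezoidal integration of the ROC curve; agrees with the
    rank formulation to floating-point precision."""
    fpr, tpr = roc_curve_points(y_true, scores)
    return float(np.trapezoid(tpr, fpr))


def _report_from_scores(y_true: np.ndarray, scores: np.ndarray,
                        threshold: float) -> MetricsReport:
    preds = (scores >= threshold).astype(int)
    report = compute_metrics(confusion_from_predictions(y_true, preds))
    if len(np.unique(y_true)) == 2:
        report.AUC = roc_auc(y_true, scores)
    else:
        warnings.warn("single-class truth; AUC omitted", stacklevel=3)
    return report


def evaluate_holdout(
    train: FeatureTable,
    test: FeatureTable,
    sparams: Optional[SISOMAPParams] = None,
    bparams: Optional[BoostParams] = None,
    threshold: float = 0.5,
    transductive: bool = False,
    standardize: bool = False,
) -> MetricsReport:
    """Fit embedding + classifier on ``train``, score ``test``.

    With ``transductive=True`` the embedding is refit on train and test
    jointly (label-free distances for test pairs) instead of using the
    inductive out-of-sample projection.
    """
    sparams = sparams or SISOMAPParams()
    bparams = bparams or BoostParams()
    if train.y is None or test.y is None:
        raise ValueError("both tables need labels for holdout evaluation")
    if train.n_features != test.n_features:
        raise ValueError("train/test feature columns do not match")

    X_train, X_test = train.X, test.X
    if standardize:
        mu, sd = X_train.mean(axis=0), X_train.std(axis=0)
        sd[sd == 0] = 1.0
        X_train = (X_train - mu) / sd
        X_test = (X_test - mu) / sd
    fit_table = FeatureTable(ids=train.ids, X=X_train, y=train.y)

    if transductive:
        Y_train, Y_test = sisomap_fit_transductive(fit_table, X_test, sparams)
    else:
        model = sisomap_fit(fit_table, sparams)
        Y_train = model.Y
        Y_test = sisomap_transform(model, X_test)
    clf = fit_classifier(Y_train, train.y, bparams)
    scores = predict_proba(clf, Y_test)
    return _report_from_scores(test.y, scores, threshold)


def cross_validate(
    table: FeatureTable,
    sparams: Optional[SISOMAPParams] = None,
    bparams: Optional[BoostParams] = None,
    cv: Optional[CVConfig] = None,
    threshold: float = 0.5,
    transductive: bool = False,
) -> CVResult:
    """Repeated stratified k-fold CV with leakage-safe per-fold embedding.

    Per repeat the embedding is refit on each training fold and the test
    fold is projected out-of-sample; fold predictions are pooled into one
    report per repeat, then averaged (with standard deviations) over
    repeats.  Repeat r uses seed ``base_seed + r``.
    """
    sparams = sparams or SISOMAPParams()
    bparams = bparams or BoostParams()
    cv = cv or CVConfig()
    if table.y is None:
        raise ValueError("cross-validation requires labels")
    y = table.y
    counts = np.bincount(y, minlength=2)
    if counts.min() == 0:
        raise ValueError("both classes must be present")
    if cv.stratified and cv.folds > counts.min():
        raise ValueError(
            f"stratified {cv.folds}-fold CV infeasible: minority class has "
            f"only {counts.min()} samples"
        )

    per_repeat = []
    for rep in range(cv.repeats):
        seed = cv.base_seed + rep
        if cv.stratified:
            splitter = StratifiedKFold(cv.folds, shuffle=True, random_state=seed)
        else:
            splitter = KFold(cv.folds, shuffle=True, random_state=seed)
        scores = np.empty(table.n_samples)
        for train_idx, test_idx in splitter.split(table.X, y):
            sub = FeatureTable(
                ids=[table.ids[i] for i in train_idx],
                X=table.X[train_idx],
                y=y[train_idx],
            )
            rep_bparams = BoostParams(
                n_trees=bparams.n_trees,
                learning_rate=bparams.learning_rate,
                max_depth=bparams.max_depth,
                random_seed=seed,
            )
            if transductive:
                Y_train, Y_test = sisomap_fit_transductive(
                    sub, table.X[test_idx], sparams
                )
            else:
                model = sisomap_fit(sub, sparams)
                Y_train = model.Y
                Y_test = sisomap_transform(model, table.X[test_idx])
            clf = fit_classifier(Y_train, y[train_idx], rep_bparams)
            scores[test_idx] = predict_proba(clf, Y_test)
        per_repeat.append(_report_from_scores(y, scores, threshold))

    keys = ["SEN", "SPE", "PRE", "F1", "ACC", "MCC"]
    if all(r.AUC is not None for r in per_repeat):
        keys.append("AUC")
    values = {k: [r.as_dict()[k] for r in per_repeat] for k in keys}
    mean = {k: float(np.mean(v)) for k, v in values.items()}
    std = {k: float(np.std(v)) for k, v in values.items()}
    return CVResult(mean=mean, std=std, per_repeat=per_repeat)
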