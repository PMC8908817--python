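"""Ensemble training, cross-validation and confusion-matrix evaluation.

Two bootstrap-aggregated tree ensembles are compared: a random forest
(each split considers a random sqrt(p) feature subset) and bagged trees
(every split sees all p features) — the one structural difference between
them.  Class-imbalance penalties enter as class weights on the training
criterion.  Evaluation pools out-of-fold predictions from a stratified
4-fold cross-validation into one confusion matrix and reports one-vs-rest
precision, recall and F1 per class plus the macro (overall) F1, the mean
of the per-class F1 scores.

The printed multiclass accuracy is the standard sum-of-diagonal over
total.  Per-class 0/0 ratios (e.g. a class never predicted) are reported
as 0 with a warning rather than NaN.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import BaggingClassifier, RandomForestClassifier
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier

from .imbalance import PenaltyMatrix, compute_penalties
from .preprocess import (
    LABEL_COL,
    apply_pca,
    apply_standardizer,
    drop_correlated,
    find_correlated,
    fit_pca,
    fit_standardizer,
)

__all__ = [
    "ModelSpec",
    "EvaluationReport",
    "GridReport",
    "crossval",
    "holdout_validate",
    "metrics_from_confusion",
    "paired_ttest",
    "run_experiment_grid",
    "format_report",
]

FAMILIES = ("random_forest", "bagged_trees", "subspace_knn")


@dataclass(frozen=True)
class ModelSpec:
    family: str = "bagged_trees"
    n_trees: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")


def build_estimator(spec: ModelSpec, class_weight: dict[int, float] | None = None):
    """Instantiate the configured ensemble.

    ``bagged_trees`` differs from ``random_forest`` only in considering all
    features at every split (``max_features=None`` vs ``"sqrt"``).
    """
    if spec.family in ("random_forest", "bagged_trees"):
        return RandomForestClassifier(
            n_estimators=spec.n_trees,
            max_features="sqrt" if spec.family == "random_forest" else None,
            bootstrap=True,
            class_weight=class_weight,
            random_state=spec.seed,
            n_jobs=1,
        )
    # optional extra: random-subspace KNN (no class-weight support)
    if class_weight is not None:
        warnings.warn("subspace_knn ignores class penalties", stacklevel=2)
    return BaggingClassifier(
        estimator=KNeighborsClassifier(),
        n_estimators=spec.n_trees,
        max_features=0.5,
        bootstrap=False,
        bootstrap_features=True,
        random_state=spec.seed,
        n_jobs=1,
    )


@dataclass
class EvaluationReport:
    confusion: np.ndarray
    classes: list[int]
    accuracy: float
    precision: dict[int, float]
    recall: dict[int, float]
    f1: dict[int, float]
    overall_f1: float
    fold_accuracies: list[float]
    fingerprint: str
    notes: list[str] = field(default_factory=list)


def _fingerprint(payload: dict) -> str:
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def metrics_from_confusion(cm: np.ndarray) -> dict:
    """One-vs-rest metrics from a K x K confusion matrix.

    For class i: TP = cm[i, i], FP = column sum - TP, FN = row sum - TP,
    TN = the rest.  precision = TP/(TP+FP), recall = TP/(TP+FN),
    F1 = harmonic mean of the two, each 0 when its denominator vanishes;
    accuracy = trace / total; overall F1 = mean of the class F1 scores.
    """
    cm = np.asarray(cm, dtype=float)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1] or cm.size == 0:
        raise ValueError("confusion matrix must be square and non-empty")
    total = cm.sum()
    if total <= 0:
        raise ValueError("confusion matrix must contain at least one sample")
    tp = np.diag(cm)
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(tp + fp > 0, tp / np.where(tp + fp > 0, tp + fp, 1), 0.0)
        recall = np.where(tp + fn > 0, tp / np.where(tp + fn > 0, tp + fn, 1), 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall / np.where(denom > 0, denom, 1), 0.0)
    return {
        "accuracy": float(tp.sum() / total),
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "overall_f1": float(f1.mean()),
    }


def _split_xy(m: pd.DataFrame):
    x = m[[c for c in m.columns if c != LABEL_COL]]
    y = m[LABEL_COL].to_numpy(dtype=int)
    return x, y


def _prep_fold(train, test, use_pca, pca_var, corr_screen):
    std = fit_standardizer(train)
    tr = apply_standardizer(std, train)
    te = apply_standardizer(std, test)
    if corr_screen:
        pairs = find_correlated(tr)
        tr = drop_correlated(tr, pairs)
        te = te[tr.columns]
    if use_pca:
        model = fit_pca(tr, pca_var)
        tr = apply_pca(model, tr)
        te = apply_pca(model, te)
    return tr, te


def _resolve_weights(penalty, y_train, classes):
    if penalty is None:
        return None
    if isinstance(penalty, PenaltyMatrix):
        return penalty.weights
    if penalty == "auto":
        counts = {c: int((y_train == c).sum()) for c in classes}
        return compute_penalties(counts).weights
    raise ValueError("penalty must be None, 'auto' or a PenaltyMatrix")


def crossval(
    features: pd.DataFrame,
    model: ModelSpec,
    k: int = 4,
    penalty="auto",
    use_pca: bool = False,
    pca_var: float = 0.95,
    corr_screen: bool = False,
    paper_mode: bool = False,
    seed: int = 0,
) -> EvaluationReport:
    """k-fold cross-validation with per-fold preprocessing and penalties.

    Default mode is leakage-free: standardizer, correlation screen, PCA and
    penalties are fitted on each training fold only, and folds are
    stratified so every fold contains the rare class.  ``paper_mode`` fits
    preprocessing and penalties once on the full matrix and uses plain
    random partitions, failing loudly if a training fold lacks a class.
    """
    x_all, y_all = _split_xy(features)
    classes = sorted(np.unique(y_all))
    if not paper_mode:
        for c in classes:
            if (y_all == c).sum() < k:
                raise ValueError(
                    f"class {c} has fewer than {k} windows; stratified CV impossible"
                )
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)

    if paper_mode:
        std = fit_standardizer(features)
        global_std = apply_standardizer(std, features)
        if corr_screen:
            global_std = drop_correlated(global_std, find_correlated(global_std))
        if use_pca:
            pca_model = fit_pca(global_std, pca_var)
            global_std = apply_pca(pca_model, global_std)
        if penalty == "auto":
            penalty = compute_penalties({c: int((y_all == c).sum()) for c in classes})

    y_true_all, y_pred_all, fold_accuracies, notes = [], [], [], []
    for fold, (tr_idx, te_idx) in enumerate(splitter.split(features, y_all)):
        if paper_mode:
            tr = global_std.iloc[tr_idx]
            te = global_std.iloc[te_idx]
        else:
            tr, te = _prep_fold(
                features.iloc[tr_idx], features.iloc[te_idx], use_pca, pca_var, corr_screen
            )
        x_tr, y_tr = _split_xy(tr)
        x_te, y_te = _split_xy(te)
        if paper_mode and len(np.unique(y_tr)) < len(classes):
            raise ValueError(
                "a class is absent from a training fold; use stratified mode"
            )
        weights = _resolve_weights(penalty, y_tr, classes)
        est = build_estimator(
            ModelSpec(model.family, model.n_trees, model.seed + fold), weights
        )
        est.fit(x_tr.to_numpy(), y_tr)
        pred = est.predict(x_te.to_numpy())
        y_true_all.append(y_te)
        y_pred_all.append(pred)
        fold_accuracies.append(float((pred == y_te).mean()))

    y_true = np.concatenate(y_true_all)
    y_pred = np.concatenate(y_pred_all)
    cm = _sk_confusion(y_true, y_pred, labels=classes)
    metrics = metrics_from_confusion(cm)
    fp = _fingerprint(
        {
            "model": model,
            "k": k,
            "penalty": "none" if penalty is None else "eq1",
            "pca": use_pca,
            "pca_var": pca_var,
            "corr_screen": corr_screen,
            "paper_mode": paper_mode,
            "seed": seed,
            "n": len(features),
        }
    )
    return EvaluationReport(
        confusion=cm,
        classes=classes,
        accuracy=metrics["accuracy"],
        precision={c: float(v) for c, v in zip(classes, metrics["precision"])},
        recall={c: float(v) for c, v in zip(classes, metrics["recall"])},
        f1={c: float(v) for c, v in zip(classes, metrics["f1"])},
        overall_f1=metrics["overall_f1"],
        fold_accuracies=fold_accuracies,
        fingerprint=fp,
        notes=notes,
    )


def holdout_validate(
    train_features: pd.DataFrame,
    test_features: pd.DataFrame,
    model: ModelSpec,
    penalty="auto",
    use_pca: bool = False,
    pca_var: float = 0.95,
    corr_screen: bool = False,
    seed: int = 0,
) -> EvaluationReport:
    """Train on one individual's session, evaluate on another's.

    Nothing from the test session enters the fit.  Classes missing from
    the test session score 0 with a warning rather than crashing.
    """
    train_cols = list(train_features.columns)
    if train_cols != list(test_features.columns):
        raise ValueError("train and test feature schemas differ")
    tr, te = _prep_fold(train_features, test_features, use_pca, pca_var, corr_screen)
    x_tr, y_tr = _split_xy(tr)
    x_te, y_te = _split_xy(te)
    classes = sorted(np.unique(y_tr))
    weights = _resolve_weights(penalty, y_tr, classes)
    est = build_estimator(ModelSpec(model.family, model.n_trees, seed), weights)
    est.fit(x_tr.to_numpy(), y_tr)
    pred = est.predict(x_te.to_numpy())
    notes = []
    missing = sorted(set(classes) - set(np.unique(y_te)))
    if missing:
        msg = f"classes {missing} absent from the test session; their metrics are 0"
        warnings.warn(msg, stacklevel=2)
        notes.append(msg)
    cm = _sk_confusion(y_te, pred, labels=classes)
    metrics = metrics_from_confusion(cm)
    acc = float((pred == y_te).mean())
    fp = _fingerprint(
        {
            "model": model,
            "holdout": True,
            "penalty": "none" if penalty is None else "eq1",
            "pca": use_pca,
            "corr_screen": corr_screen,
            "seed": seed,
            "n_train": len(train_features),
            "n_test": len(test_features),
        }
    )
    return EvaluationReport(
        confusion=cm,
        classes=classes,
        accuracy=metrics["accuracy"],
        precision={c: float(v) for c, v in zip(classes, metrics["precision"])},
        recall={c: float(v) for c, v in zip(classes, metrics["recall"])},
        f1={c: float(v) for c, v in zip(classes, metrics["f1"])},
        overall_f1=metrics["overall_f1"],
        fold_accuracies=[acc],
        fingerprint=fp,
        notes=notes,
    )


def paired_ttest(metric_runs_a: Sequence[float], metric_runs_b: Sequence[float]):
    """Two-tailed paired-samples t-test on matched metric runs.

    Returns (t, p).  Identical inputs (zero difference everywhere) give
    p = 1 by convention; a constant nonzero shift with no variance gives
    p = 0 (an infinitely strong paired effect).
    """
    a = np.asarray(metric_runs_a, dtype=float)
    b = np.asarray(metric_runs_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired runs must have equal length")
    n = a.size
    if n < 2:
        raise ValueError("insufficient pairs")
    d = a - b
    if np.allclose(d, 0.0):
        return 0.0, 1.0
    sd = d.std(ddof=1)
    if sd == 0.0:
        return float(np.inf * np.sign(d[0])), 0.0
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return float(t), float(p)


@dataclass
class GridReport:
    #: (window_s, use_pca, family) -> one EvaluationReport per repeat
    cells: dict
    #: pairwise paired t-tests between matched cells
    comparisons: list[dict]


_GRID_METRICS = ("accuracy", "f1_1", "f1_2", "f1_3", "overall_f1")


def _cell_metric(report: EvaluationReport, metric: str) -> float:
    if metric == "accuracy":
        return report.accuracy
    if metric == "overall_f1":
        return report.overall_f1
    cls = int(metric.split("_")[1])
    return report.f1.get(cls, 0.0)


def run_experiment_grid(
    sessions: Mapping[float, pd.DataFrame],
    families: Sequence[str] = ("bagged_trees",),
    pca_options: Sequence[bool] = (False, True),
    repeats: int = 3,
    k: int = 4,
    penalty="auto",
    n_trees: int = 100,
    seed: int = 0,
) -> GridReport:
    """Run the window-length x PCA x model grid with repeated CV.

    ``sessions`` maps window length (s) to the feature matrix built at
    that window length.  Each repeat re-partitions the folds with a fresh
    seed; matched cells (PCA vs none at a window, short vs long window at
    a PCA setting, family vs family) are compared with two-tailed paired
    t-tests on accuracy and every F1 when ``repeats >= 2``.
    """
    cells: dict = {}
    for window_s, fm in sessions.items():
        for use_pca in pca_options:
            for family in families:
                reports = [
                    crossval(
                        fm,
                        ModelSpec(family, n_trees, seed),
                        k=k,
                        penalty=penalty,
                        use_pca=use_pca,
                        seed=seed + r,
                    )
                    for r in range(repeats)
                ]
                cells[(float(window_s), bool(use_pca), family)] = reports

    comparisons: list[dict] = []
    if repeats >= 2:

        def compare(kind, key_a, key_b, context):
            for metric in _GRID_METRICS:
                runs_a = [_cell_metric(rep, metric) for rep in cells[key_a]]
                runs_b = [_cell_metric(rep, metric) for rep in cells[key_b]]
                t, p = paired_ttest(runs_a, runs_b)
                comparisons.append(
                    {
                        "kind": kind,
                        "metric": metric,
                        "a": key_a,
                        "b": key_b,
                        "mean_a": float(np.mean(runs_a)),
                        "mean_b": float(np.mean(runs_b)),
                        "t": t,
                        "p": p,
                        **context,
                    }
                )

        windows = sorted({key[0] for key in cells})
        for window_s in windows:
            for family in families:
                if (window_s, False, family) in cells and (window_s, True, family) in cells:
                    compare(
                        "pca_vs_none",
                        (window_s, True, family),
                        (window_s, False, family),
                        {"window_s": window_s, "family": family},
                    )
        for use_pca in pca_options:
            for family in families:
                for w_a, w_b in itertools.combinations(windows, 2):
                    compare(
                        "window_vs_window",
                        (w_a, bool(use_pca), family),
                        (w_b, bool(use_pca), family),
                        {"pca": bool(use_pca), "family": family},
                    )
        for window_s in windows:
            for use_pca in pca_options:
                for f_a, f_b in itertools.combinations(families, 2):
                    compare(
                        "family_vs_family",
                        (window_s, bool(use_pca), f_a),
                        (window_s, bool(use_pca), f_b),
                        {"window_s": window_s, "pca": bool(use_pca)},
                    )
    return GridReport(cells=cells, comparisons=comparisons)


def format_report(report: EvaluationReport) -> str:
    """Human-readable confusion matrix plus metric table."""
    lines = ["confusion matrix (rows = true, columns = predicted):"]
    header = "      " + "".join(f"pred {c:>2} " for c in report.classes)
    lines.append(header)
    for i, c in enumerate(report.classes):
        row = "".join(f"{int(v):>8}" for v in report.confusion[i])
        lines.append(f"true {c}{row}")
    lines.append(f"accuracy      {report.accuracy:.4f}")
    for c in report.classes:
        lines.append(
            f"class {c}: precision {report.precision[c]:.4f}  "
            f"recall {report.recall[c]:.4f}  F1 {report.f1[c]:.4f}"
        )
    lines.append(f"overall F1    {report.overall_f1:.4f}")
    lines.append(f"fold accuracies {['%.4f' % a for a in report.fold_accuracies]}")
    lines.append(f"config fingerprint {report.fingerprint}")
    for note in report.notes:
        lines.append(f"note: {note}")
    return "\n".join(lines)
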