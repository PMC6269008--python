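"""Classifier quality measures: CCR, MCC, ROC/Youden, 10-fold CV.

CCR (corrected classification rate) is the balanced accuracy
(TP/N1 + TN/N0)/2, where N1/N0 are all positive/negative instances; MCC is
the Matthews correlation over the 2x2 confusion table. ROC curves are built
by a threshold sweep over the unique scores with ties grouped, and the
operating cutoff is chosen by Youden's J = max(TPR - FPR).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import math

import numpy as np
import pandas as pd

from .dti import CLASS_NEG, CLASS_POS, DecisionTreeModel, InductionParams, induce, predict_frame


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 confusion table; positives are CNSp+."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")
        if self.tp + self.tn + self.fp + self.fn == 0:
            raise ValueError("empty confusion table")

    @property
    def n0(self) -> int:
        """All negative instances."""
        return self.tn + self.fp

    @property
    def n1(self) -> int:
        """All positive instances."""
        return self.tp + self.fn

    @staticmethod
    def from_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> "ConfusionCounts":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        return ConfusionCounts(
            tp=int(((y_true == CLASS_POS) & (y_pred == CLASS_POS)).sum()),
            tn=int(((y_true == CLASS_NEG) & (y_pred == CLASS_NEG)).sum()),
            fp=int(((y_true == CLASS_NEG) & (y_pred == CLASS_POS)).sum()),
            fn=int(((y_true == CLASS_POS) & (y_pred == CLASS_NEG)).sum()),
        )

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.tn + other.tn, self.fp + other.fp, self.fn + other.fn
        )


def ccr(c: ConfusionCounts) -> float:
    """Corrected classification rate (TP/N1 + TN/N0)/2, in [0, 1]."""
    if c.n0 == 0 or c.n1 == 0:
        raise ValueError("CCR undefined when a class is absent")
    return 0.5 * (c.tp / c.n1 + c.tn / c.n0)


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient, in [-1, 1]; 0 when degenerate."""
    denom = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    if denom == 0:
        return 0.0
    return (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)


@dataclass
class RocCurve:
    """ROC points from a threshold sweep, with AUC and the Youden-J cutoff."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray  # matching cutoffs; predict + iff score >= threshold
    auc: float
    youden_cutoff: float
    youden_j: float


def roc_curve(scores: np.ndarray, labels: np.ndarray) -> RocCurve:
    """ROC from continuous scores (higher = more CNSp+-like).

    Thresholds sweep the unique scores descending with ties grouped; the
    curve runs from (0,0) to (1,1) and the AUC is the trapezoidal area,
    which equals the Mann-Whitney concordant-pair probability.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n1 = int((labels == CLASS_POS).sum())
    n0 = int((labels == CLASS_NEG).sum())
    if n0 == 0 or n1 == 0:
        raise ValueError("ROC needs both classes present")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    pos = (labels[order] == CLASS_POS).astype(int)
    # group ties: cumulative counts at the last index of each tied block
    distinct = np.r_[np.nonzero(np.diff(s))[0], len(s) - 1]
    cum_pos = np.cumsum(pos)
    tps = cum_pos[distinct]
    fps = (distinct + 1) - tps
    tpr = np.r_[0.0, tps / n1]
    fpr = np.r_[0.0, fps / n0]
    thresholds = np.r_[np.inf, s[distinct]]
    auc = float(np.trapezoid(tpr, fpr))
    j = tpr - fpr
    best_j = j.max()
    # ties -> lower threshold (more sensitive operating point)
    candidates = np.nonzero(np.isclose(j, best_j))[0]
    pick = candidates[np.argmin(thresholds[candidates])]
    return RocCurve(
        fpr=fpr,
        tpr=tpr,
        thresholds=thresholds,
        auc=auc,
        youden_cutoff=float(thresholds[pick]),
        youden_j=float(best_j),
    )


def youden_cutoff(roc: RocCurve) -> tuple[float, float]:
    """(cutoff, J) of the Youden-optimal operating point of a ROC curve."""
    return roc.youden_cutoff, roc.youden_j


@dataclass
class FoldResult:
    test_index: np.ndarray
    y_true: np.ndarray
    y_pred: np.ndarray
    confusion: ConfusionCounts
    ccr: float | None
    mcc: float


@dataclass
class CrossValidationResult:
    """Per-fold predictions plus pooled counts and averaged metrics."""

    folds: list[FoldResult]
    pooled: ConfusionCounts
    mean_ccr: float
    mean_mcc: float
    pooled_ccr: float
    pooled_mcc: float
    fold_assignment: np.ndarray
    seed: int
    n_reshuffles: int = 0
    models: list[DecisionTreeModel] = field(default_factory=list)


def stratified_folds(
    y: np.ndarray, n_folds: int, seed: int, stratified: bool = True
) -> np.ndarray:
    """Fold id (0..n_folds-1) per instance, random under ``seed``.

    Stratification deals each class round-robin across folds after an
    in-class shuffle, keeping class balance as even as the counts allow.
    """
    rng = np.random.default_rng(seed)
    n = len(y)
    assignment = np.empty(n, dtype=int)
    if stratified:
        for cls in np.unique(y):
            idx = np.flatnonzero(y == cls)
            rng.shuffle(idx)
            assignment[idx] = np.arange(len(idx)) % n_folds
        # rotate fold labels per class start so fold sizes stay balanced
    else:
        idx = rng.permutation(n)
        assignment[idx] = np.arange(n) % n_folds
    return assignment


def cross_validate_10fold(
    inducer: Callable[[pd.DataFrame, np.ndarray, InductionParams], DecisionTreeModel],
    X: pd.DataFrame,
    y: np.ndarray,
    params: InductionParams,
    seed: int,
    n_folds: int = 10,
    stratified: bool = True,
    keep_models: bool = False,
) -> CrossValidationResult:
    """10-fold cross-validation: train on nine folds, test on the held-out one.

    Every instance is tested exactly once. Reported performance is the
    average of the per-fold CCR/MCC (the protocol's "average risk" reading);
    metrics over the pooled confusion counts are also returned. If a training
    partition ends up single-class the folds are re-randomized under a
    derived seed (counted in ``n_reshuffles``).
    """
    y = np.asarray(y)
    if len(y) < 2 * n_folds:
        raise ValueError(f"need at least {2 * n_folds} instances for {n_folds}-fold CV")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    attempt = 0
    while True:
        fold_seed = seed + 7919 * attempt
        assignment = stratified_folds(y, n_folds, fold_seed, stratified)
        train_ok = all(
            len(np.unique(y[assignment != f])) == 2 for f in range(n_folds)
        )
        if train_ok or attempt > 50:
            break
        attempt += 1
    folds: list[FoldResult] = []
    pooled: ConfusionCounts | None = None
    models: list[DecisionTreeModel] = []
    for f in range(n_folds):
        test = np.flatnonzero(assignment == f)
        train = np.flatnonzero(assignment != f)
        model = inducer(X.iloc[train], y[train], params)
        y_pred = predict_frame(model, X.iloc[test])
        conf = ConfusionCounts.from_predictions(y[test], y_pred)
        fold_ccr = ccr(conf) if (conf.n0 > 0 and conf.n1 > 0) else None
        folds.append(
            FoldResult(
                test_index=test,
                y_true=y[test],
                y_pred=y_pred,
                confusion=conf,
                ccr=fold_ccr,
                mcc=mcc(conf),
            )
        )
        pooled = conf if pooled is None else pooled + conf
        if keep_models:
            models.append(model)
    assert pooled is not None
    ccrs = [f.ccr for f in folds if f.ccr is not None]
    return CrossValidationResult(
        folds=folds,
        pooled=pooled,
        mean_ccr=float(np.mean(ccrs)),
        mean_mcc=float(np.mean([f.mcc for f in folds])),
        pooled_ccr=ccr(pooled),
        pooled_mcc=mcc(pooled),
        fold_assignment=assignment,
        seed=seed,
        n_reshuffles=attempt,
        models=models,
    )


def metrics_dict(cv: CrossValidationResult) -> dict:
    """JSON-ready summary of a cross-validation run."""
    return {
        "mean_ccr": cv.mean_ccr,
        "mean_mcc": cv.mean_mcc,
        "pooled_ccr": cv.pooled_ccr,
        "pooled_mcc": cv.pooled_mcc,
        "pooled_confusion": {
            "tp": cv.pooled.tp, "tn": cv.pooled.tn,
            "fp": cv.pooled.fp, "fn": cv.pooled.fn,
        },
        "per_fold": [
            {"ccr": f.ccr, "mcc": f.mcc, "n_test": int(len(f.test_index))}
            for f in cv.folds
        ],
        "seed": cv.seed,
        "n_reshuffles": cv.n_reshuffles,
    }


def cross_validate(
    inducer, X, y, params, seed, **kwargs
) -> CrossValidationResult:  # pragma: no cover - thin alias
    """Alias for :func:`cross_validate_10fold` with configurable folds."""
    return cross_validate_10fold(inducer, X, y, params, seed, **kwargs)


def default_inducer(X: pd.DataFrame, y: np.ndarray, params: InductionParams) -> DecisionTreeModel:
    """Paradigm-dispatching inducer usable directly with the CV driver."""
    return induce(X, y, params)
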