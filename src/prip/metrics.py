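"""Evaluation: confusion-based metrics, ROC/AUROC, cross-validation and the
window-length scan.

SN = TP/(TP+FN), SP = TN/(TN+FP), ACC = (TP+TN)/N and

    MCC = (TP*TN - FP*FN) / sqrt((TN+FN)(TN+FP)(TP+FN)(TP+FP))

are computed from hard calls at a probability threshold (score >= threshold
counts as positive); AUROC is the trapezoidal area under the ROC curve with
tied scores grouped into single steps.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

METRIC_NAMES = ("SN", "SP", "ACC", "MCC", "AUROC")


@dataclass
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


def confusion(y, scores, threshold: float = 0.5) -> ConfusionCounts:
    """Hard-call confusion counts; predicted positive iff score >= threshold."""
    y = np.asarray(y)
    scores = np.asarray(scores, dtype=float)
    if y.shape != scores.shape:
        raise ValueError("y and scores must have equal length")
    pred = scores >= threshold
    pos = y == 1
    return ConfusionCounts(
        TP=int((pred & pos).sum()),
        FP=int((pred & ~pos).sum()),
        TN=int((~pred & ~pos).sum()),
        FN=int((~pred & pos).sum()),
    )


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); returning NaN")
        return float("nan")
    return num / den


def sn(c: ConfusionCounts) -> float:
    """Sensitivity TP/(TP+FN)."""
    return _ratio(c.TP, c.TP + c.FN, "SN")


def sp(c: ConfusionCounts) -> float:
    """Specificity TN/(TN+FP)."""
    return _ratio(c.TN, c.TN + c.FP, "SP")


def acc(c: ConfusionCounts) -> float:
    """Accuracy (TP+TN)/N."""
    return _ratio(c.TP + c.TN, c.total, "ACC")


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient."""
    den = (
        (c.TN + c.FN) * (c.TN + c.FP) * (c.TP + c.FN) * (c.TP + c.FP)
    )
    if den == 0:
        warnings.warn("MCC undefined (zero denominator); returning NaN")
        return float("nan")
    return (c.TP * c.TN - c.FP * c.FN) / math.sqrt(den)


@dataclass
class ROCCurve:
    """(fpr, tpr) points from (0,0) to (1,1) plus the trapezoidal area."""

    fpr: np.ndarray
    tpr: np.ndarray
    auroc: float

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("fpr\ttpr\n")
            for f, t in zip(self.fpr, self.tpr):
                fh.write(f"{float(f)!r}\t{float(t)!r}\n")


def roc_auroc(y, scores) -> ROCCurve:
    """ROC by threshold sweep over distinct scores, ties grouped."""
    y = np.asarray(y)
    scores = np.asarray(scores, dtype=float)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes present")
    order = np.argsort(-scores, kind="stable")
    ys = y[order]
    ss = scores[order]
    # group equal scores into one step
    distinct = np.r_[np.flatnonzero(np.diff(ss)), len(ss) - 1]
    tps = np.cumsum(ys == 1)[distinct]
    fps = np.cumsum(ys == 0)[distinct]
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    auroc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(fpr, tpr, auroc)


# ---------------------------------------------------------------------------
# Cross-validation

@dataclass
class CVReport:
    """Per-fold and mean metrics of a k-fold cross-validation."""

    fold_metrics: list[dict[str, float]]
    fold_counts: list[ConfusionCounts]
    seed: int

    @property
    def k(self) -> int:
        return len(self.fold_metrics)

    @property
    def means(self) -> dict[str, float]:
        return {
            m: float(np.mean([f[m] for f in self.fold_metrics]))
            for m in METRIC_NAMES
        }

    def summary_table(self) -> str:
        lines = ["fold\t" + "\t".join(METRIC_NAMES)]
        for i, f in enumerate(self.fold_metrics, 1):
            lines.append(str(i) + "\t" + "\t".join(f"{f[m]:.2f}" for m in METRIC_NAMES))
        mean = self.means
        lines.append("mean\t" + "\t".join(f"{mean[m]:.2f}" for m in METRIC_NAMES))
        return "\n".join(lines)


def stratified_folds(y, k: int, seed: int) -> np.ndarray:
    """Deterministic stratified fold assignment at the sample level.

    Indices of each class are shuffled and dealt round-robin, so fold sizes
    differ by at most one per class.
    """
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    folds = np.empty(len(y), dtype=np.int64)
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        folds[idx] = np.arange(len(idx)) % k
    return folds


def grouped_folds(y, groups, k: int, seed: int) -> np.ndarray:
    """Chain-level folds: whole groups assigned greedily, balancing the
    positive count per fold (largest groups first)."""
    y = np.asarray(y)
    groups = np.asarray(groups)
    rng = np.random.default_rng(seed)
    uniq = list(dict.fromkeys(groups.tolist()))
    rng.shuffle(uniq)
    pos_per_group = {gname: int(y[groups == gname].sum()) for gname in uniq}
    order = sorted(uniq, key=lambda gname: -pos_per_group[gname])
    load = np.zeros(k)
    fold_of_group = {}
    for gname in order:
        f = int(np.argmin(load))
        fold_of_group[gname] = f
        load[f] += pos_per_group[gname] + 1e-3
    return np.array([fold_of_group[gname] for gname in groups], dtype=np.int64)


def evaluate_scores(y, scores, threshold: float = 0.5) -> dict[str, float]:
    c = confusion(y, scores, threshold)
    return {
        "SN": sn(c), "SP": sp(c), "ACC": acc(c), "MCC": mcc(c),
        "AUROC": roc_auroc(y, scores).auroc,
    }


def kfold_cv(
    X,
    y,
    trainer: Callable[[np.ndarray, np.ndarray], "object"],
    k: int = 5,
    seed: int = 0,
    threshold: float = 0.5,
    groups=None,
) -> CVReport:
    """k rounds of train-on-(k-1)/test-on-1 with stratified folds.

    ``trainer(X_train, y_train)`` must return an object with
    ``predict_proba(X) -> scores``.  Mean-of-folds metrics are reported.
    """
    X = np.asarray(X)
    y = np.asarray(y)
    if k < 2:
        raise ValueError("k must be >= 2")
    if groups is None:
        folds = stratified_folds(y, k, seed)
    else:
        folds = grouped_folds(y, groups, k, seed)
    fold_metrics, fold_counts = [], []
    for f in range(k):
        test = folds == f
        model = trainer(X[~test], y[~test])
        scores = np.asarray(model.predict_proba(X[test]))
        fold_metrics.append(evaluate_scores(y[test], scores, threshold))
        fold_counts.append(confusion(y[test], scores, threshold))
    return CVReport(fold_metrics, fold_counts, seed)


def window_scan(
    chains,
    run_cv: Callable[[Sequence, int], float],
    lengths: Iterable[int] = range(21, 40, 2),
) -> dict[int, float]:
    """Mean CV AUROC for each window length of the scan grid.

    ``run_cv(chains, n)`` executes the full pipeline (embedding training,
    featurization, boosting, cross-validation) at half-window ``n`` and
    returns the mean AUROC; see :func:`prip.pipeline.cv_auroc_for_length`.
    """
    out = {}
    for L in lengths:
        if L < 3 or L % 2 == 0:
            raise ValueError(f"window length must be odd and >= 3, got {L}")
        out[L] = float(run_cv(chains, (L - 1) // 2))
    return out
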