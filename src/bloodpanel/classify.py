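"""Sample-class discrimination and single-gene classifiers.

Viral-vs-bacterial discrimination runs 2-cluster K-means on the per-sample
(NG_V, NG_B) score vectors; the cluster whose centroid has the larger
NG_V - NG_B is labelled the viral-pattern class.  For very small inputs
(n <= 10) the partition of minimum within-cluster sum of squares is found
exactly by enumeration; otherwise Lloyd's algorithm with restarts is used.

Single-gene biomarkers come in two flavours: a univariate logistic model
F(x) = 1 / (1 + exp(-(a0 + a1 x))) fitted on fold-change values of one gene,
and a plain fold-threshold rule (positive iff FC strictly above a cutoff).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.linear_model import LogisticRegression

__all__ = [
    "ConfusionMetrics",
    "KMeansFit",
    "LogisticModel",
    "confusion_metrics",
    "kmeans_discriminate",
    "fit_logistic",
    "predict_logistic",
    "threshold_classify",
    "treatment_response",
]

_EXACT_KMEANS_MAX_N = 10


@dataclass(frozen=True)
class ConfusionMetrics:
    """Binary-classification counts with the derived precision/recall/F1.

    Degenerate denominators yield 0 (a classifier that never predicts the
    positive class has precision 0 by convention, not an error).
    """

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def precision(self) -> float:
        d = self.tp + self.fp
        return self.tp / d if d else 0.0

    @property
    def recall(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else 0.0

    @property
    def f1(self) -> float:
        d = 2 * self.tp + self.fp + self.fn
        return 2 * self.tp / d if d else 0.0

    def to_dict(self, ndigits: int | None = None) -> dict:
        p, r, f = self.precision, self.recall, self.f1
        if ndigits is not None:
            p, r, f = (round(v, ndigits) for v in (p, r, f))
        return {
            "tp": self.tp, "fn": self.fn, "fp": self.fp, "tn": self.tn,
            "precision": p, "recall": r, "f1": f,
        }


def confusion_metrics(
    predicted: Sequence, truth: Sequence, positive_class
) -> ConfusionMetrics:
    """Count TP/FN/FP/TN of ``predicted`` against ``truth``."""
    pred = np.asarray(predicted)
    true = np.asarray(truth)
    if pred.size == 0:
        raise ValueError("empty label vectors")
    if pred.shape != true.shape:
        raise ValueError("predicted and truth must have equal length")
    pp = pred == positive_class
    tp_ = true == positive_class
    return ConfusionMetrics(
        tp=int(np.sum(pp & tp_)),
        fn=int(np.sum(~pp & tp_)),
        fp=int(np.sum(pp & ~tp_)),
        tn=int(np.sum(~pp & ~tp_)),
    )


@dataclass
class KMeansFit:
    centroids: np.ndarray  # 2 x 2, rows = clusters, cols = (ng_v, ng_b)
    assignment: np.ndarray  # cluster index per sample
    label_map: dict[int, str]
    inertia: float
    sample_ids: list[str] = field(default_factory=list)

    @property
    def labels(self) -> pd.Series:
        return pd.Series(
            [self.label_map[int(a)] for a in self.assignment],
            index=self.sample_ids or None,
            name="predicted",
        )


def _exact_two_partition(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Minimum within-cluster-SS 2-partition by enumeration (first optimum kept)."""
    n = points.shape[0]
    best_assign: np.ndarray | None = None
    best_ss = np.inf
    # fix sample 0 in cluster 0 to halve the search space
    for mask in range(1, 2 ** (n - 1)):
        assign = np.zeros(n, dtype=int)
        for j in range(1, n):
            assign[j] = (mask >> (j - 1)) & 1
        ss = 0.0
        for c in (0, 1):
            pts = points[assign == c]
            if len(pts):
                ss += float(((pts - pts.mean(axis=0)) ** 2).sum())
        if ss < best_ss - 1e-12:
            best_ss = ss
            best_assign = assign
    assert best_assign is not None
    return best_assign, best_ss


def kmeans_discriminate(
    scores: pd.DataFrame,
    seed: int | None = 0,
    n_init: int = 10,
    viral_label: str = "viral",
    bacterial_label: str = "bacterial",
) -> KMeansFit:
    """2-cluster K-means on (ng_v, ng_b) with a viral/bacterial label map.

    ``scores`` needs columns ``ng_v`` and ``ng_b``.  The cluster whose
    centroid has the larger ng_v - ng_b becomes the viral-pattern class.
    Raw counts are clustered (both axes share the 0..panel-size unit).
    """
    pts = scores[["ng_v", "ng_b"]].to_numpy(dtype=float)
    n = pts.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples to cluster")
    if np.all(pts == pts[0]):
        raise ValueError("all score vectors identical; clustering is degenerate")

    if n <= _EXACT_KMEANS_MAX_N:
        assign, inertia = _exact_two_partition(pts)
        centroids = np.vstack([
            pts[assign == c].mean(axis=0) if np.any(assign == c) else pts.mean(axis=0)
            for c in (0, 1)
        ])
    else:
        km = KMeans(n_clusters=2, n_init=n_init, random_state=seed)
        assign = km.fit_predict(pts)
        centroids = km.cluster_centers_
        inertia = float(km.inertia_)

    sep = centroids[:, 0] - centroids[:, 1]  # ng_v - ng_b per centroid
    viral_cluster = int(np.argmax(sep))
    label_map = {
        viral_cluster: viral_label,
        1 - viral_cluster: bacterial_label,
    }
    return KMeansFit(
        centroids=centroids,
        assignment=np.asarray(assign),
        label_map=label_map,
        inertia=float(inertia),
        sample_ids=list(scores.index),
    )


@dataclass
class LogisticModel:
    """Univariate logistic classifier F(x) = 1/(1 + exp(-(a0 + a1 x)))."""

    a0: float
    a1: float
    feature: str = "fc"
    transform: str = "linear"  # or "log2"
    decision_threshold: float = 0.5
    positive_class: str = "case"
    negative_class: str = "control"

    def to_dict(self) -> dict:
        return dict(self.__dict__)

    @classmethod
    def from_dict(cls, payload: dict) -> "LogisticModel":
        return cls(**payload)


def fit_logistic(
    fc_values: Sequence[float],
    labels: Sequence,
    positive_class="case",
    feature: str = "fc",
    log2_feature: bool = False,
    ridge: float = 1e-4,
    decision_threshold: float = 0.5,
) -> LogisticModel:
    """Maximum-likelihood fit of the univariate logistic model.

    A weak ridge penalty on the slope (default 1e-4) keeps the coefficients
    finite when the classes are perfectly separable; for non-separable data
    it is numerically indistinguishable from the plain ML fit.
    ``log2_feature=True`` fits on log2(fc) instead of linear fc (recorded in
    the model so prediction applies the same transform).
    """
    x = np.asarray(fc_values, dtype=float)
    y = (np.asarray(labels) == positive_class).astype(int)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training data must contain both classes")
    if log2_feature:
        x = np.log2(x)
    neg = [c for c in np.unique(np.asarray(labels)) if c != positive_class]
    clf = LogisticRegression(
        C=1.0 / ridge, solver="lbfgs", tol=1e-12, max_iter=100000
    )
    clf.fit(x.reshape(-1, 1), y)
    return LogisticModel(
        a0=float(clf.intercept_[0]),
        a1=float(clf.coef_[0, 0]),
        feature=feature,
        transform="log2" if log2_feature else "linear",
        decision_threshold=decision_threshold,
        positive_class=positive_class,
        negative_class=str(neg[0]) if neg else "negative",
    )


def predict_logistic(
    model: LogisticModel, fc_values: Sequence[float]
) -> tuple[np.ndarray, np.ndarray]:
    """Probabilities F(x) and hard labels (positive iff F(x) >= threshold)."""
    x = np.asarray(fc_values, dtype=float)
    if model.transform == "log2":
        x = np.log2(x)
    z = model.a0 + model.a1 * x
    probs = 1.0 / (1.0 + np.exp(-z))
    labels = np.where(
        probs >= model.decision_threshold, model.positive_class, model.negative_class
    )
    return labels, probs


def threshold_classify(
    fc_values: Sequence[float], fold_threshold: float
) -> np.ndarray:
    """Positive iff fold change strictly exceeds the fold threshold."""
    return np.asarray(fc_values, dtype=float) > fold_threshold


def treatment_response(
    pre_values: pd.Series,
    post_values: pd.Series,
    fold_reduction: float = 2.0,
) -> pd.Series:
    """Responder flags from paired pre/post log2 values per patient.

    Responder iff ``pre - post >= log2(fold_reduction)`` (boundary counts as
    response).  Patients without both measurements are excluded with a
    warning.
    """
    if fold_reduction <= 1.0:
        raise ValueError("fold_reduction must exceed 1")
    paired = pre_values.index.intersection(post_values.index)
    unpaired = pre_values.index.symmetric_difference(post_values.index)
    if len(unpaired):
        warnings.warn(f"unpaired patients excluded: {sorted(unpaired)}", stacklevel=2)
    delta = pre_values.loc[paired] - post_values.loc[paired]
    flags = delta >= np.log2(fold_reduction)
    flags.name = "responder"
    return flags
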