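"""Evaluation metrics and rank-based model selection.

MCC (the study's main metric) and AUC are implemented from their defining
formulas — the confusion-matrix correlation and the Mann-Whitney
probability that a random positive outranks a random negative — and are
cross-checked against scikit-learn in the test suite.  The model-selection
machinery computes Friedman-style average ranks (mid-rank ties) over a
datasets x methods score matrix and aggregates rankings with Borda's
method; the significance tests fed by these ranks (Friedman, Hommel,
Wilcoxon) are deliberately left to standard statistical packages.

Also here: the dataset-characterisation statistics (imbalance ratio,
intra-/inter-class pixel distances, silhouette) used to describe how hard
a two-class image collection is.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .data import LabeledImageSet

__all__ = [
    "ConfusionCounts",
    "ScoredPredictions",
    "DatasetStats",
    "mcc",
    "auc",
    "average_ranks",
    "borda_aggregate",
    "marginal_value_ranking",
    "imbalance_ratio",
    "class_distance_stats",
    "silhouette",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts with melanoma as the positive class."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionCounts":
        y_true = np.asarray(y_true, dtype=int)
        y_pred = np.asarray(y_pred, dtype=int)
        return cls(
            tp=int(((y_true == 1) & (y_pred == 1)).sum()),
            tn=int(((y_true == 0) & (y_pred == 0)).sum()),
            fp=int(((y_true == 0) & (y_pred == 1)).sum()),
            fn=int(((y_true == 1) & (y_pred == 0)).sum()),
        )

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class ScoredPredictions:
    """Per-image melanoma probability, hard label and truth."""

    melanoma_prob: np.ndarray
    pred_label: np.ndarray
    true_label: np.ndarray

    def __post_init__(self) -> None:
        self.melanoma_prob = np.asarray(self.melanoma_prob, dtype=float)
        self.pred_label = np.asarray(self.pred_label, dtype=int)
        self.true_label = np.asarray(self.true_label, dtype=int)
        if not (len(self.melanoma_prob) == len(self.pred_label) == len(self.true_label)):
            raise ValueError("prediction arrays must have equal length")
        if not np.all(np.isfinite(self.melanoma_prob)):
            raise ValueError("probabilities must be finite")

    def confusion(self) -> ConfusionCounts:
        return ConfusionCounts.from_predictions(self.true_label, self.pred_label)


@dataclass(frozen=True)
class DatasetStats:
    """Characterisation of a two-class image set."""

    imbalance_ratio: float
    intra_class: float
    inter_class: float
    dist_ratio: float
    silhouette: float


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient.

    (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)); in [-1, 1] with
    1 a perfect prediction.  When any denominator factor is zero (a
    degenerate truth or prediction margin) the convention is 0.
    """
    if c.total == 0:
        raise ValueError("cannot compute MCC of empty counts")
    tp, tn, fp, fn = (float(x) for x in (c.tp, c.tn, c.fp, c.fn))
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / np.sqrt(denom)


def auc(preds: ScoredPredictions | tuple) -> float:
    """Area under the ROC curve via the Mann-Whitney statistic.

    The probability that a uniformly drawn positive is scored above a
    uniformly drawn negative, ties counting one half — identical to the
    trapezoidal area under the ROC curve.
    """
    if isinstance(preds, ScoredPredictions):
        y, s = preds.true_label, preds.melanoma_prob
    else:
        y, s = np.asarray(preds[0], dtype=int), np.asarray(preds[1], dtype=float)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: both classes must be present")
    ranks = rankdata(s)  # mid-ranks handle ties with weight 1/2
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def average_ranks(scores: np.ndarray) -> np.ndarray:
    """Friedman-style average ranks of methods over datasets.

    ``scores`` is (datasets, methods), higher = better.  Within each
    dataset methods are ranked 1 = best with tied scores receiving the
    mean of their positions; the ranks are averaged over datasets.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2:
        raise ValueError("scores must be a (datasets, methods) matrix")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite (no missing values)")
    ranks = rankdata(-scores, axis=1)
    return ranks.mean(axis=0)


def borda_aggregate(rankings: list[list]) -> list:
    """Borda consensus of ordered preference lists.

    With positions 0-indexed from the top, an element at position p earns
    M - 1 - p points in each ranking (the winner gets M - 1, the last
    0); the consensus orders elements by descending total score, ties
    broken by element identifier.
    """
    if not rankings:
        raise ValueError("need at least one ranking")
    elements = set(rankings[0])
    m = len(elements)
    for r in rankings:
        if set(r) != elements or len(r) != m:
            raise ValueError("all rankings must order the same element set")
    score: dict = {e: 0 for e in elements}
    for r in rankings:
        for pos, e in enumerate(r):
            score[e] += m - 1 - pos
    return sorted(elements, key=lambda e: (-score[e], str(e)))


def marginal_value_ranking(config_ranks: dict, value_of) -> list:
    """Order hyper-parameter values by the mean average-rank of the
    configurations that use them (lower mean rank = better).

    ``config_ranks`` maps configuration -> average rank; ``value_of``
    extracts the marginal value from a configuration.  This is the
    documented marginalisation used to read per-dimension consensus
    orders out of a full-grid rank row.
    """
    groups: dict = {}
    for cfg, rk in config_ranks.items():
        groups.setdefault(value_of(cfg), []).append(rk)
    means = {v: float(np.mean(rs)) for v, rs in groups.items()}
    return sorted(means, key=lambda v: (means[v], str(v)))


def imbalance_ratio(labels) -> float:
    """Majority-to-minority class count ratio (>= 1)."""
    labels = np.asarray(labels, dtype=int)
    n0 = int((labels == 0).sum())
    n1 = int((labels == 1).sum())
    if n0 == 0 or n1 == 0:
        raise ValueError("imbalance ratio undefined: a class is missing")
    return max(n0, n1) / min(n0, n1)


def _pairwise_distances(x: np.ndarray) -> np.ndarray:
    from sklearn.metrics import pairwise_distances

    return pairwise_distances(x, metric="euclidean")


def _flatten_images(images: LabeledImageSet, pixel_scale: float) -> np.ndarray:
    return np.stack([img.reshape(-1) for img in images.images]) * pixel_scale


def class_distance_stats(
    images: LabeledImageSet,
    pixel_scale: float = 255.0,
    max_pairs: int = 10**6,
    seed: int = 0,
) -> DatasetStats:
    """Intra-/inter-class mean Euclidean pixel distances and their ratio.

    Distances are computed on flattened images with pixels scaled to
    [0, 255].  ``intra`` pools within-class pairs over both classes,
    ``inter`` averages across-class pairs; when both vanish the ratio is
    1 by convention.  Pair sets larger than ``max_pairs`` are subsampled
    (seeded).
    """
    labels = images.labels
    for cls_label in (0, 1):
        if (labels == cls_label).sum() < 2:
            raise ValueError("each class needs >= 2 images for intra-class distances")
    x = _flatten_images(images, pixel_scale)
    n = len(x)
    if n * (n - 1) // 2 > max_pairs:
        rng = np.random.default_rng(seed)
        keep = rng.choice(n, size=int(np.sqrt(2 * max_pairs)) + 1, replace=False)
        x, labels = x[keep], labels[keep]
    d = _pairwise_distances(x)
    same = labels[:, None] == labels[None, :]
    triu = np.triu(np.ones_like(same, dtype=bool), k=1)
    intra = float(d[same & triu].mean())
    inter = float(d[~same & triu].mean())
    ratio = 1.0 if intra == 0 and inter == 0 else intra / inter
    return DatasetStats(
        imbalance_ratio=imbalance_ratio(labels),
        intra_class=intra,
        inter_class=inter,
        dist_ratio=ratio,
        silhouette=silhouette(images),
    )


def silhouette(images: LabeledImageSet, pixel_scale: float = 255.0) -> float:
    """Mean silhouette score of the two pixel-space classes.

    For each image, a = mean distance to its own class (excluding itself)
    and b = mean distance to the other class; the score is the mean of
    (b - a) / max(a, b), in [-1, 1].
    """
    labels = images.labels
    for cls_label in (0, 1):
        if (labels == cls_label).sum() < 2:
            raise ValueError("each class needs >= 2 images for the silhouette")
    x = _flatten_images(images, pixel_scale)
    d = _pairwise_distances(x)
    scores = np.empty(len(x))
    for i in range(len(x)):
        own = (labels == labels[i]) & (np.arange(len(x)) != i)
        other = labels != labels[i]
        a = d[i, own].mean()
        b = d[i, other].mean()
        m = max(a, b)
        scores[i] = 0.0 if m == 0 else (b - a) / m
    return float(scores.mean())
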