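"""Cluster validity indices, consensus k selection and hold-out validation.

The initial clustering is run over a grid of k values; each partition is
scored with three standard internal validity indices (Davies-Bouldin —
lower is better; Calinski-Harabasz — higher is better; silhouette — in
[-1, 1], higher is better) computed on the trajectories as fixed-length
Euclidean vectors, and the chosen k is the one with the best mean rank
across the three indices (ties go to the smallest k).

Final trajectory labels are additionally validated by training a sequence
classifier on 70% of the labelled trajectories and scoring the 30%
hold-out: the confusion matrix and support-weighted F1 quantify how
learnable (hence how internally coherent) the label assignment is. Classes
with fewer than two members cannot be split and are excluded. The
classifier is pluggable (any fit/predict object); the default is a
1-nearest-neighbour classifier under the soft-DTW distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn import metrics as _skm
from sklearn.model_selection import train_test_split

from .sdtw import soft_dtw_pairwise

__all__ = [
    "davies_bouldin",
    "calinski_harabasz",
    "silhouette",
    "select_k",
    "KSelectionReport",
    "SoftDTW1NN",
    "validate_with_classifier",
    "ValidationReport",
]


def _check_clusters(series, labels, min_clusters=2):
    X = np.asarray(series, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(labels)
    if len(y) != X.shape[0]:
        raise ValueError("labels must match the number of series")
    uniq = np.unique(y)
    if len(uniq) < min_clusters:
        raise ValueError(f"need at least {min_clusters} clusters, got {len(uniq)}")
    return X, y, uniq


def davies_bouldin(series, labels) -> float:
    """Davies-Bouldin index (0 is best): mean over clusters of the worst
    ratio of summed within-cluster scatters to centroid separation."""
    X, y, _ = _check_clusters(series, labels)
    return float(_skm.davies_bouldin_score(X, y))


def calinski_harabasz(series, labels) -> float:
    """Calinski-Harabasz ratio of between- to within-cluster dispersion
    (higher is better); +inf sentinel when within-dispersion is zero."""
    X, y, uniq = _check_clusters(series, labels)
    W = 0.0
    for c in uniq:
        sub = X[y == c]
        W += float(((sub - sub.mean(axis=0)) ** 2).sum())
    if W == 0.0:
        warnings.warn("zero within-cluster dispersion; CH index is infinite")
        return float("inf")
    return float(_skm.calinski_harabasz_score(X, y))


def _silhouette_from_distances(D, y) -> float:
    n = len(y)
    s = np.zeros(n)
    uniq = np.unique(y)
    for i in range(n):
        own = y[i]
        same = (y == own)
        if same.sum() == 1:
            s[i] = 0.0  # singleton-cluster convention
            continue
        a = D[i, same & (np.arange(n) != i)].mean()
        b = min(D[i, y == c].mean() for c in uniq if c != own)
        s[i] = (b - a) / max(a, b) if max(a, b) > 0 else 0.0
    return float(s.mean())


def silhouette(series, labels, metric: str = "euclidean",
               gamma: float = 1.0) -> float:
    """Mean silhouette coefficient in [-1, 1]; size-1 clusters score 0.

    ``metric`` is Euclidean on the trajectory vectors by default; the
    "softdtw" option scores cohesion/separation under the soft-DTW
    discrepancy instead.
    """
    X, y, _ = _check_clusters(series, labels)
    if metric == "euclidean":
        return float(_skm.silhouette_score(X, y))
    if metric == "softdtw":
        D = soft_dtw_pairwise(X, X, gamma=gamma)
        D = 0.5 * (D + D.T)
        return _silhouette_from_distances(D, y)
    raise ValueError(f"unknown metric {metric!r}")


@dataclass
class KSelectionReport:
    """Per-k validity indices and the consensus choice."""

    grid: list
    db: dict
    ch: dict
    sil: dict
    chosen_k: int

    def to_frame(self) -> pd.DataFrame:
        rows = [{"k": k, "davies_bouldin": self.db[k],
                 "calinski_harabasz": self.ch[k], "silhouette": self.sil[k],
                 "chosen": k == self.chosen_k} for k in self.grid]
        return pd.DataFrame(rows)


def select_k(db: dict, ch: dict, sil: dict) -> KSelectionReport:
    """Consensus choice of k by mean rank across the three indices.

    Davies-Bouldin is ranked ascending (smaller better), Calinski-Harabasz
    and silhouette descending; the k with the best (smallest) mean rank
    wins, ties broken toward the smallest k.
    """
    grid = sorted(db)
    if not grid or sorted(ch) != grid or sorted(sil) != grid:
        raise ValueError("index maps must share one nonempty k grid")
    from scipy.stats import rankdata
    db_r = rankdata([db[k] for k in grid])
    ch_r = rankdata([-ch[k] for k in grid])
    sil_r = rankdata([-sil[k] for k in grid])
    mean_rank = (db_r + ch_r + sil_r) / 3.0
    chosen = grid[int(np.argmin(mean_rank))]  # argmin takes first == smallest k
    return KSelectionReport(grid=list(grid), db=dict(db), ch=dict(ch),
                            sil=dict(sil), chosen_k=chosen)


class SoftDTW1NN:
    """1-nearest-neighbour sequence classifier under the soft-DTW distance.

    Dependency-free default backend for hold-out validation; any object
    with the same fit/predict surface (e.g. a recurrent network wrapper)
    can be plugged in instead.
    """

    def __init__(self, gamma: float = 1.0):
        self.gamma = gamma

    def fit(self, X, y):
        self._X = np.asarray(X, dtype=float)
        self._y = np.asarray(y)
        return self

    def predict(self, X):
        D = soft_dtw_pairwise(np.asarray(X, dtype=float), self._X, self.gamma)
        return self._y[D.argmin(axis=1)]


@dataclass
class ValidationReport:
    """Hold-out classification report over trajectory labels."""

    confusion: pd.DataFrame
    f1_weighted: float
    excluded_classes: set
    split_frac: float
    seed: int
    classes: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "classes": [str(c) for c in self.classes],
            "confusion": self.confusion.to_numpy().tolist(),
            "f1_weighted": self.f1_weighted,
            "excluded_classes": sorted(str(c) for c in self.excluded_classes),
            "split_frac": self.split_frac,
            "seed": self.seed,
        }


def validate_with_classifier(series, labels, split_frac: float = 0.30,
                             seed: int = 0, classifier=None) -> ValidationReport:
    """Stratified hold-out validation of a trajectory labelling.

    Classes with fewer than two members are excluded up front (they cannot
    appear on both sides of the split). Trains on 1 - split_frac of the
    remaining series and reports the confusion matrix and support-weighted
    F1 on the hold-out.
    """
    X = np.asarray(series, dtype=float)
    y = np.asarray(labels)
    if len(y) != X.shape[0]:
        raise ValueError("labels must match the number of series")
    vals, counts = np.unique(y, return_counts=True)
    excluded = {v for v, c in zip(vals, counts) if c < 2}
    keep = ~np.isin(y, list(excluded)) if excluded else np.ones(len(y), bool)
    if not keep.any():
        raise ValueError("every class has fewer than two members")
    Xk, yk = X[keep], y[keep]
    classes = [v for v in vals if v not in excluded]
    if len(classes) < 2:
        raise ValueError("need at least two classes with >= 2 members")
    Xtr, Xte, ytr, yte = train_test_split(
        Xk, yk, test_size=split_frac, random_state=seed, stratify=yk)
    clf = classifier if classifier is not None else SoftDTW1NN()
    clf.fit(Xtr, ytr)
    pred = clf.predict(Xte)
    cm = _skm.confusion_matrix(yte, pred, labels=classes)
    f1 = _skm.f1_score(yte, pred, labels=classes, average="weighted",
                       zero_division=0)
    cm_df = pd.DataFrame(cm, index=[str(c) for c in classes],
                         columns=[str(c) for c in classes])
    return ValidationReport(confusion=cm_df, f1_weighted=float(f1),
                            excluded_classes=excluded, split_frac=split_frac,
                            seed=seed, classes=list(classes))
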