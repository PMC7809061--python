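"""Readouts: spike-count features, winner-take-all decoding, Victor-Purpura
spike-train distance, correlation features, and the PCA+KNN harness.

The winner-take-all ("biomimetic") decoder reports the orientation of the
cortical group with the highest summed PY spike count in the analysis
window.  Machine-learning decoding reduces per-unit spike counts (or other
feature rows) to z = 3 principal components fit on the training folds only
and classifies with a k = 5 nearest-neighbour vote under fivefold
cross-validation.  Spike timing is quantified with the Victor-Purpura
metric: the minimal cost of editing one train into the other with
insertions/deletions at cost 1 and shifts at cost q |dt| (q in 1/ms).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Callable, Sequence

import numpy as np
from sklearn.decomposition import PCA
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier


# ---------------------------------------------------------------------------
# rasters
# ---------------------------------------------------------------------------


@dataclass
class SpikeRaster:
    """Event-list spike raster of one layer for one trial."""

    units: np.ndarray  # (n_events,) unit ids
    times_ms: np.ndarray  # (n_events,) sorted ascending
    n_units: int
    duration_ms: float
    meta: dict[str, Any] = field(default_factory=dict)

    @classmethod
    def from_matrix(cls, spikes: np.ndarray, dt_ms: float, **meta: Any) -> "SpikeRaster":
        t_idx, units = np.nonzero(spikes)
        return cls(units, t_idx * dt_ms, spikes.shape[1], spikes.shape[0] * dt_ms, meta)

    def unit_train(self, unit: int) -> np.ndarray:
        return self.times_ms[self.units == unit]

    def counts(self, t_end_ms: float | None = None, t_start_ms: float = 0.0) -> np.ndarray:
        """Per-unit spike counts with ``t_start <= t < t_end``."""
        t_end = self.duration_ms if t_end_ms is None else t_end_ms
        mask = (self.times_ms >= t_start_ms) & (self.times_ms < t_end)
        return np.bincount(self.units[mask], minlength=self.n_units)


def spike_counts(raster: SpikeRaster, window_ms: float) -> np.ndarray:
    """Per-unit spike counts in [0, window_ms)."""
    return raster.counts(t_end_ms=window_ms)


# ---------------------------------------------------------------------------
# winner-take-all decoder
# ---------------------------------------------------------------------------


def biomimetic_decode(
    raster: SpikeRaster,
    group_of: np.ndarray,
    orientations_deg: Sequence[float],
    window_ms: float | None = None,
) -> float | None:
    """Orientation of the highest-count cortical group (winner-take-all).

    Ties break toward the smallest orientation; an all-silent raster yields
    ``None`` (an explicit no-detection, scored as incorrect).
    """
    counts = raster.counts(t_end_ms=window_ms)
    group_counts = np.bincount(group_of, weights=counts, minlength=len(orientations_deg))
    if group_counts.max() == 0:
        return None
    return float(orientations_deg[int(np.argmax(group_counts))])


# ---------------------------------------------------------------------------
# Victor-Purpura distance
# ---------------------------------------------------------------------------


def vp_distance(train_a: np.ndarray, train_b: np.ndarray, q: float = 1.0) -> float:
    """Victor-Purpura spike-train distance by the standard dynamic program.

    Insertion/deletion cost 1, shift cost ``q * |t_a - t_b|`` (q in 1/ms).
    O(n_a * n_b) time.
    """
    if q < 0:
        raise ValueError("q must be >= 0")
    a = np.sort(np.asarray(train_a, dtype=float))
    b = np.sort(np.asarray(train_b, dtype=float))
    na, nb = len(a), len(b)
    if na == 0 or nb == 0:
        return float(na + nb)
    prev = np.arange(nb + 1, dtype=float)
    for i in range(1, na + 1):
        cur = np.empty(nb + 1)
        cur[0] = i
        shift = q * np.abs(a[i - 1] - b)  # cost of matching a[i-1] to each b[j-1]
        for j in range(1, nb + 1):
            cur[j] = min(prev[j] + 1.0, cur[j - 1] + 1.0, prev[j - 1] + shift[j - 1])
        prev = cur
    return float(prev[nb])


def vpd_features(trains: Sequence[np.ndarray], q: float = 1.0) -> np.ndarray:
    """Symmetric pairwise VPd matrix; row i is trial i's feature vector."""
    n = len(trains)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = vp_distance(trains[i], trains[j], q)
    return D


# ---------------------------------------------------------------------------
# correlation features
# ---------------------------------------------------------------------------


def correlation_features(traces: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial Pearson correlations with leave-one-out class mean templates.

    ``traces`` is (n_trials, n_samples); feature j of trial i is the
    correlation of trial i's trace with the mean trace of class j, excluding
    trial i itself from its own class template.  Zero-variance traces are
    dropped.

    Returns (features (n_kept, n_classes), kept_index).
    """
    traces = np.asarray(traces, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    keep = traces.std(axis=1) > 0
    idx = np.nonzero(keep)[0]
    X = np.zeros((len(idx), len(classes)))
    sums = {c: traces[labels == c].sum(axis=0) for c in classes}
    ns = {c: int((labels == c).sum()) for c in classes}
    for row, i in enumerate(idx):
        for jc, c in enumerate(classes):
            if labels[i] == c and ns[c] > 1:
                template = (sums[c] - traces[i]) / (ns[c] - 1)
            else:
                template = sums[c] / ns[c]
            if template.std() == 0:
                X[row, jc] = 0.0
            else:
                X[row, jc] = np.corrcoef(traces[i], template)[0, 1]
    return X, idx


# ---------------------------------------------------------------------------
# PCA + KNN harness
# ---------------------------------------------------------------------------


@dataclass
class DecodeResult:
    """Pooled cross-validated decoding outcome."""

    predictions: np.ndarray
    labels: np.ndarray
    accuracy: float
    confusion: np.ndarray  # (n_classes, n_classes) counts, rows = true
    classes: np.ndarray
    window_ms: float | None = None

    def to_dict(self) -> dict[str, Any]:
        return {
            "accuracy": self.accuracy,
            "window_ms": self.window_ms,
            "classes": self.classes.tolist(),
            "confusion": self.confusion.tolist(),
        }


def _confusion(y_true: np.ndarray, y_pred: np.ndarray, classes: np.ndarray) -> np.ndarray:
    lut = {c: i for i, c in enumerate(classes)}
    M = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        if p in lut:
            M[lut[t], lut[p]] += 1
    return M


def pca_knn_classify(
    features: np.ndarray,
    labels: np.ndarray,
    z: int = 3,
    k: int = 5,
    folds: int = 5,
    rng: np.random.Generator | int | None = None,
    window_ms: float | None = None,
    n_repeats: int = 1,
) -> DecodeResult:
    """z-component PCA + k-NN vote under stratified fivefold cross-validation.

    Principal axes are fit on the training rows of each fold only (no
    leakage).  ``z`` larger than the feature rank is capped.  With
    ``n_repeats`` > 1 the cross-validation is repeated over independent fold
    assignments and the accuracy averaged (repeated stratified CV), which
    removes most of the fold-assignment variance from the estimate; the
    returned predictions and confusion matrix are those of the first repeat.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    master = np.random.default_rng(rng)
    folds = min(folds, int(np.bincount(np.searchsorted(classes, y)).min()))
    if folds < 2:
        raise ValueError("need at least two trials per class for cross-validation")

    accs = []
    first_preds = None
    for _ in range(n_repeats):
        seed = int(master.integers(2**31 - 1))
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        preds = np.empty_like(y)
        for train, test in skf.split(X, y):
            z_eff = min(z, X.shape[1], len(train) - 1)
            pca = PCA(n_components=z_eff)
            Xtr = pca.fit_transform(X[train])
            Xte = pca.transform(X[test])
            knn = KNeighborsClassifier(n_neighbors=min(k, len(train)))
            knn.fit(Xtr, y[train])
            preds[test] = knn.predict(Xte)
        accs.append(float(np.mean(preds == y)))
        if first_preds is None:
            first_preds = preds
    acc = float(np.mean(accs))
    return DecodeResult(
        first_preds, y, acc, _confusion(y, first_preds, classes), classes, window_ms
    )


def wta_result(
    true_labels: Sequence[float],
    predicted: Sequence[float | None],
    classes: Sequence[float],
    window_ms: float | None = None,
) -> DecodeResult:
    """Wrap winner-take-all predictions into a :class:`DecodeResult`."""
    y = np.asarray(true_labels, dtype=float)
    p = np.array([np.nan if v is None else v for v in predicted], dtype=float)
    classes = np.asarray(classes, dtype=float)
    acc = float(np.mean(p == y))
    return DecodeResult(p, y, acc, _confusion(y, p, classes), classes, window_ms)


def performance_curve(
    windows_ms: Sequence[float],
    decode_at: Callable[[float], DecodeResult],
) -> tuple[np.ndarray, list[DecodeResult]]:
    """Accuracy as a function of an expanding analysis window.

    ``decode_at(window)`` must return the pooled :class:`DecodeResult` for
    that window; windows must be sorted ascending.
    """
    w = np.asarray(windows_ms, dtype=float)
    if np.any(np.diff(w) < 0):
        raise ValueError("windows must be sorted ascending")
    results = [decode_at(float(x)) for x in w]
    return np.array([r.accuracy for r in results]), results


def expanding_windows(t_max_ms: float = 180.0, n: int = 60) -> np.ndarray:
    """The n progressively expanding windows from 0 to t_max."""
    return np.linspace(t_max_ms / n, t_max_ms, n)
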