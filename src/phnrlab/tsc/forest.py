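"""Time series forest: tree ensemble on random-interval summary features.

Each tree samples ``round(sqrt(T))`` random intervals (minimum length 3
samples) and summarizes each by its mean, standard deviation and OLS
slope; a binary decision tree minimizing cross-entropy is grown on the
resulting 3-per-interval feature vector.  Prediction is a majority vote
across trees, with ties resolved to the negative class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from sklearn.tree import DecisionTreeClassifier

__all__ = ["TSFModel", "interval_features", "tsf_fit", "tsf_predict"]

MIN_INTERVAL = 3


@dataclass(frozen=True)
class TSFModel:
    trees: tuple[DecisionTreeClassifier, ...]
    intervals: tuple[tuple[tuple[int, int], ...], ...]  # per tree: (start, end)
    classes: tuple  # (negative, positive), vote ties -> classes[0]
    series_length: int
    n_estimators: int
    seed: int


def _interval_slope(segment: np.ndarray) -> np.ndarray:
    """OLS slope of each row of ``segment`` against 0..L-1 (closed form)."""
    L = segment.shape[-1]
    t = np.arange(L, dtype=float)
    t_c = t - t.mean()
    denom = float((t_c**2).sum())
    if denom == 0.0:
        return np.zeros(segment.shape[:-1])
    return (segment * t_c).sum(axis=-1) / denom


def interval_features(X: np.ndarray, intervals) -> np.ndarray:
    """Mean, SD and slope of each interval for each series (row) of X."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    feats = []
    for start, end in intervals:
        seg = X[:, start:end]
        feats.append(seg.mean(axis=1))
        feats.append(seg.std(axis=1, ddof=0))
        feats.append(_interval_slope(seg))
    return np.column_stack(feats)


def _sample_intervals(T: int, n_intervals: int, rng: np.random.Generator):
    out = []
    for _ in range(n_intervals):
        length = int(rng.integers(MIN_INTERVAL, T + 1))
        start = int(rng.integers(0, T - length + 1))
        out.append((start, start + length))
    return tuple(out)


def tsf_fit(train_series, train_labels, n_estimators: int = 100,
            seed: int = 0, n_intervals: int | None = None) -> TSFModel:
    """Fit a time series forest on equal-length series."""
    X = np.atleast_2d(np.asarray(train_series, dtype=float))
    y = np.asarray(train_labels)
    T = X.shape[1]
    if T < MIN_INTERVAL:
        raise ValueError(f"series length {T} shorter than minimum interval {MIN_INTERVAL}")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("TSF requires at least 2 classes in training labels")
    k = n_intervals if n_intervals is not None else max(1, round(math.sqrt(T)))
    rng = np.random.default_rng(seed)
    trees, tree_intervals = [], []
    for i in range(n_estimators):
        intervals = _sample_intervals(T, k, rng)
        feats = interval_features(X, intervals)
        tree = DecisionTreeClassifier(criterion="log_loss",
                                      random_state=int(rng.integers(2**31 - 1)))
        tree.fit(feats, y)
        trees.append(tree)
        tree_intervals.append(intervals)
    return TSFModel(tuple(trees), tuple(tree_intervals),
                    tuple(sorted(classes.tolist())), T, n_estimators, seed)


def tsf_predict(model: TSFModel, series) -> tuple[object, float]:
    """(label, vote fraction) for one series; even vote splits go to the
    negative (first, sorted) class."""
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size != model.series_length:
        raise ValueError(
            f"series length {x.size} does not match training length "
            f"{model.series_length}")
    votes = {c: 0 for c in model.classes}
    for tree, intervals in zip(model.trees, model.intervals):
        feats = interval_features(x[None, :], intervals)
        votes[tree.predict(feats)[0]] += 1
    neg = model.classes[0]
    best = max(votes.items(), key=lambda kv: (kv[1], kv[0] == neg))
    return best[0], votes[best[0]] / len(model.trees)


def tsf_predict_batch(model: TSFModel, X) -> list:
    """Vectorized majority-vote prediction for a batch of series."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.series_length:
        raise ValueError("series length mismatch")
    counts = {c: np.zeros(X.shape[0], dtype=int) for c in model.classes}
    for tree, intervals in zip(model.trees, model.intervals):
        pred = tree.predict(interval_features(X, intervals))
        for c in model.classes:
            counts[c] += pred == c
    neg, pos = model.classes[0], model.classes[-1]
    return [pos if counts[pos][i] > counts[neg][i] else neg
            for i in range(X.shape[0])]
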