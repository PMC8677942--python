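"""Dynamic time warping distance and 1-NN classification.

The distance is the minimum cumulative local cost over monotone warping
paths with steps {(1,0), (0,1), (1,1)}.  For univariate series the local
cost is the absolute difference (the Euclidean point distance); a squared
local cost is available as a variant.  An optional Sakoe–Chiba band of
half-width ``band`` restricts |i - j|.

The O(n·m) dynamic program is JIT-compiled with numba when available and
falls back to pure Python otherwise.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["dtw_distance", "knn_dtw_predict"]

try:  # pragma: no cover - exercised implicitly
    from numba import njit
    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f
        return wrap(args[0]) if args and callable(args[0]) else wrap


@njit(cache=True)
def _dtw_dp(x, y, band, squared):  # pragma: no cover - numba kernel
    n, m = x.shape[0], y.shape[0]
    inf = math.inf
    prev = np.full(m + 1, inf)
    curr = np.full(m + 1, inf)
    prev[0] = 0.0
    for i in range(1, n + 1):
        curr[:] = inf
        jlo, jhi = 1, m
        if band >= 0:
            jlo = max(1, i - band)
            jhi = min(m, i + band)
        for j in range(jlo, jhi + 1):
            d = abs(x[i - 1] - y[j - 1])
            if squared:
                d = d * d
            best = prev[j - 1]
            if prev[j] < best:
                best = prev[j]
            if curr[j - 1] < best:
                best = curr[j - 1]
            curr[j] = d + best
        prev, curr = curr, prev
    return prev[m]


def dtw_distance(x, y, band: int | None = None, squared: bool = False) -> float:
    """DTW distance between two univariate series.

    ``band`` is the Sakoe–Chiba half-width (None = unconstrained); it must
    be at least the length difference of the series or no path exists.
    """
    xv = np.ascontiguousarray(x, dtype=np.float64)
    yv = np.ascontiguousarray(y, dtype=np.float64)
    if xv.size == 0 or yv.size == 0:
        raise ValueError("DTW requires non-empty series")
    if band is not None:
        if band < 0:
            raise ValueError("band must be non-negative")
        if band < abs(xv.size - yv.size):
            raise ValueError(
                f"band {band} smaller than length difference "
                f"{abs(xv.size - yv.size)}; no warping path exists")
    b = -1 if band is None else int(band)
    return float(_dtw_dp(xv, yv, b, squared))


def knn_dtw_predict(train_series, train_labels, query, k: int = 1,
                    band: int | None = None, squared: bool = False):
    """Label of the k nearest training series under DTW.

    Majority vote among the k nearest; all ties (in distance and in the
    vote) resolve toward the smallest training index.
    """
    labels = list(train_labels)
    if len(labels) == 0:
        raise ValueError("empty training set")
    if k > len(labels):
        raise ValueError(f"k={k} exceeds training-set size {len(labels)}")
    dists = np.array([dtw_distance(s, query, band=band, squared=squared)
                      for s in train_series])
    order = np.lexsort((np.arange(dists.size), dists))  # stable: index breaks ties
    top = order[:k]
    votes: dict = {}
    for idx in top:
        votes.setdefault(labels[idx], []).append(idx)
    best = max(votes.items(), key=lambda kv: (len(kv[1]), -min(kv[1])))
    return best[0]
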