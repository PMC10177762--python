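"""Correlation-based feature subset selection (CFS) with best-first search.

Implements Hall's CFS: candidate subsets are scored by

    merit(S) = k * r_cf / sqrt(k + k (k - 1) * r_ff)

where ``k = |S|``, ``r_cf`` is the mean feature-class correlation and
``r_ff`` the mean pairwise feature-feature correlation, both measured
by symmetrical uncertainty SU(X, Y) = 2 I(X; Y) / (H(X) + H(Y)) on
equal-frequency discretized columns.  A forward best-first search over
subsets, terminating after a fixed number of consecutive non-improving
expansions, yields the selected subset — the behaviour of the WEKA
``CfsSubsetEval`` + ``BestFirst`` pairing used to produce the study's
published attribute lists.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .features import FeatureTable

__all__ = [
    "SelectionResult",
    "discretize_equal_frequency",
    "symmetrical_uncertainty",
    "cfs_merit",
    "best_first_search",
    "exhaustive_search",
]


@dataclass
class SelectionResult:
    """Selected subset (in discovery order), its merit and search trace."""

    selected: list[str]
    merit: float
    trace: list[tuple[int, float]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"selected": self.selected, "merit": self.merit,
                "trace": [[k, m] for k, m in self.trace]}


def discretize_equal_frequency(values: np.ndarray, n_bins: int = 10
                               ) -> np.ndarray:
    """Equal-frequency bin labels; ties broken by value then input order.

    The sorted column is cut into ``n_bins`` contiguous chunks whose
    sizes differ by at most one (the first ``len % n_bins`` chunks take
    the extra element).  Identical values may straddle a bin boundary —
    the stable sort resolves them by input position.  A constant column
    occupies a single bin.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot discretize an empty column")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    n = values.size
    if np.all(values == values[0]):
        return np.zeros(n, dtype=int)
    order = np.argsort(values, kind="stable")
    labels = np.empty(n, dtype=int)
    base, extra = divmod(n, n_bins)
    start = 0
    for b in range(n_bins):
        size = base + (1 if b < extra else 0)
        labels[order[start:start + size]] = b
        start += size
    return labels


def _entropy(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())


def symmetrical_uncertainty(x: np.ndarray, y: np.ndarray) -> float:
    """SU(X, Y) = 2 I(X; Y) / (H(X) + H(Y)), in [0, 1]; 0 when both constant."""
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    if x.size == 0:
        raise ValueError("empty columns")
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    joint = np.zeros((xi.max() + 1, yi.max() + 1))
    np.add.at(joint, (xi, yi), 1.0)
    hx = _entropy(joint.sum(axis=1))
    hy = _entropy(joint.sum(axis=0))
    hxy = _entropy(joint.ravel())
    mi = hx + hy - hxy
    denom = hx + hy
    if denom == 0:
        return 0.0
    return float(max(0.0, min(1.0, 2.0 * mi / denom)))


def cfs_merit(k: int, mean_feature_class_corr: float,
              mean_feature_feature_corr: float) -> float:
    """Hall's CFS merit of a k-feature subset."""
    if k < 1:
        raise ValueError("k must be >= 1")
    rcf = mean_feature_class_corr
    rff = mean_feature_feature_corr
    return float(k * rcf / np.sqrt(k + k * (k - 1) * rff))


class _MeritCache:
    """Discretized columns plus cached pairwise / class SU values."""

    def __init__(self, t: FeatureTable, n_bins: int = 10):
        self.names = list(t.feature_names)
        X = t.X
        if np.isnan(X).any():
            raise ValueError("feature table contains missing values; impute first")
        self.cols = [discretize_equal_frequency(X[:, j], n_bins)
                     for j in range(X.shape[1])]
        self.y = t.y
        self._su_class = [symmetrical_uncertainty(c, self.y) for c in self.cols]
        self._su_ff: dict[tuple[int, int], float] = {}

    def su_ff(self, i: int, j: int) -> float:
        key = (min(i, j), max(i, j))
        if key not in self._su_ff:
            self._su_ff[key] = symmetrical_uncertainty(self.cols[key[0]],
                                                       self.cols[key[1]])
        return self._su_ff[key]

    def merit(self, subset: tuple[int, ...]) -> float:
        k = len(subset)
        if k == 0:
            return 0.0
        rcf = float(np.mean([self._su_class[i] for i in subset]))
        rff = (float(np.mean([self.su_ff(i, j)
                              for i, j in combinations(subset, 2)]))
               if k > 1 else 0.0)
        return cfs_merit(k, rcf, rff)


def best_first_search(t: FeatureTable, stale_limit: int = 5,
                      n_bins: int = 10) -> SelectionResult:
    """Forward best-first search over CFS-scored subsets.

    The open list is ordered by merit (ties by insertion order, so the
    search is deterministic given the column order); expansion stops
    after ``stale_limit`` consecutive expansions that fail to improve
    the best merit seen.
    """
    if len(t.feature_names) < 2:
        raise ValueError("need at least 2 features")
    cache = _MeritCache(t, n_bins)
    n = len(cache.names)
    start: tuple[int, ...] = ()
    best_subset, best_merit = start, 0.0
    counter = 0
    heap: list[tuple[float, int, tuple[int, ...]]] = [(0.0, counter, start)]
    seen: set[frozenset[int]] = {frozenset()}
    trace: list[tuple[int, float]] = []
    stale = 0
    while heap and stale < stale_limit:
        neg_merit, _, subset = heapq.heappop(heap)
        improved = False
        in_subset = set(subset)
        for j in range(n):
            if j in in_subset:
                continue
            child = subset + (j,)
            key = frozenset(child)
            if key in seen:
                continue
            seen.add(key)
            m = cache.merit(child)
            counter += 1
            heapq.heappush(heap, (-m, counter, child))
            if m > best_merit + 1e-10:
                best_merit = m
                best_subset = child
                improved = True
                trace.append((len(child), m))
        stale = 0 if improved else stale + 1
    names = [cache.names[i] for i in best_subset]
    return SelectionResult(selected=names, merit=best_merit, trace=trace)


def exhaustive_search(t: FeatureTable, n_bins: int = 10,
                      max_features: int = 16) -> SelectionResult:
    """Merit-maximal subset by full enumeration (oracle for small tables)."""
    cache = _MeritCache(t, n_bins)
    n = len(cache.names)
    if n > max_features:
        raise ValueError(f"{n} features exceed exhaustive limit {max_features}")
    best: tuple[int, ...] = ()
    best_merit = 0.0
    for k in range(1, n + 1):
        for subset in combinations(range(n), k):
            m = cache.merit(subset)
            if m > best_merit + 1e-12:
                best_merit, best = m, subset
    return SelectionResult(selected=[cache.names[i] for i in best],
                           merit=best_merit)
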