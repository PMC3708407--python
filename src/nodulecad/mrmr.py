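"""Minimum-Redundancy Maximum-Relevance (mRMR) feature selection.

Features are ranked greedily so that the selected set S has high relevance
to the class label c, D = (1/|S|) * sum_{i in S} I(x_i; c), while keeping
low mutual redundancy, R = (1/|S|^2) * sum_{i,j in S} I(x_i; x_j) (the
double sum includes the i = j diagonal, i.e. feature entropies).  Two
stepwise criteria are supported: the difference D - R (MID, the default)
and the quotient D / R (MIQ).

Mutual information is the plug-in estimate on discretized features (log
base 2).  Continuous columns are discretized into three states by the
mean +/- one-standard-deviation thresholds of the column, which is
invariant under affine rescaling of the raw feature.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Literal, Sequence

import numpy as np

Criterion = Literal["difference", "quotient"]
_EPS_R = 1e-12  # quotient guard: D/R undefined at R = 0


@dataclasses.dataclass
class DiscreteFeatureSet:
    """Integer-coded feature columns plus binary class labels."""

    columns: np.ndarray  # (n_patterns, n_features) int
    class_labels: np.ndarray  # (n_patterns,) in {0, 1}

    def __post_init__(self) -> None:
        self.columns = np.asarray(self.columns, dtype=np.int64)
        self.class_labels = np.asarray(self.class_labels, dtype=np.int64)
        if self.columns.ndim != 2:
            raise ValueError("columns must be 2D")
        if len(self.class_labels) != self.columns.shape[0]:
            raise ValueError("label length mismatch")
        if not set(np.unique(self.class_labels)) <= {0, 1}:
            raise ValueError("labels must be binary {0,1}")

    @property
    def n_features(self) -> int:
        return self.columns.shape[1]


@dataclasses.dataclass
class MrmrResult:
    """Greedy ranking with the per-step relevance, redundancy and score."""

    ranked_indices: list[int]
    scores: list[float]
    relevance: list[float]
    redundancy: list[float]
    criterion: Criterion

    def to_dict(self, feature_names: Sequence[str] | None = None) -> dict:
        out = {
            "criterion": self.criterion,
            "ranked_indices": self.ranked_indices,
            "scores": self.scores,
            "relevance": self.relevance,
            "redundancy": self.redundancy,
        }
        if feature_names is not None:
            out["ranked_names"] = [feature_names[i] for i in self.ranked_indices]
        return out


def discretize(column: np.ndarray) -> np.ndarray:
    """Three-state coding by the mu - sigma and mu + sigma thresholds."""
    column = np.asarray(column, dtype=np.float64)
    if not np.all(np.isfinite(column)):
        raise ValueError("non-finite values")
    mu, sigma = column.mean(), column.std()
    if sigma == 0:
        return np.zeros(len(column), dtype=np.int64)
    out = np.ones(len(column), dtype=np.int64)
    out[column < mu - sigma] = 0
    out[column > mu + sigma] = 2
    return out


def mutual_information(x: np.ndarray, y: np.ndarray) -> float:
    """Plug-in mutual information in bits from the empirical joint."""
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    if len(x) < 2:
        raise ValueError("need at least 2 samples")
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    joint = np.zeros((xi.max() + 1, yi.max() + 1))
    np.add.at(joint, (xi, yi), 1.0)
    joint /= joint.sum()
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    # fsum is order-independent, so I(x,y) == I(y,x) exactly
    terms = joint[nz] * np.log2(joint[nz] / (px @ py)[nz])
    return float(math.fsum(terms))


class _MiCache:
    """Lazy cache of pairwise and feature-class mutual informations."""

    def __init__(self, table: DiscreteFeatureSet) -> None:
        self.table = table
        self._ff: dict[tuple[int, int], float] = {}
        self._fc: dict[int, float] = {}

    def feature_class(self, i: int) -> float:
        if i not in self._fc:
            self._fc[i] = mutual_information(
                self.table.columns[:, i], self.table.class_labels
            )
        return self._fc[i]

    def feature_feature(self, i: int, j: int) -> float:
        key = (min(i, j), max(i, j))
        if key not in self._ff:
            self._ff[key] = mutual_information(
                self.table.columns[:, key[0]], self.table.columns[:, key[1]]
            )
        return self._ff[key]


def relevance(s: Sequence[int], table: DiscreteFeatureSet,
              _cache: _MiCache | None = None) -> float:
    """Mean mutual information between the features in S and the class."""
    if len(s) == 0:
        raise ValueError("empty feature set")
    cache = _cache or _MiCache(table)
    return sum(cache.feature_class(i) for i in s) / len(s)


def redundancy(s: Sequence[int], table: DiscreteFeatureSet,
               _cache: _MiCache | None = None) -> float:
    """Mean pairwise mutual information within S, diagonal included."""
    if len(s) == 0:
        raise ValueError("empty feature set")
    cache = _cache or _MiCache(table)
    total = sum(cache.feature_feature(i, j) for i in s for j in s)
    return total / len(s) ** 2


def criterion_value(s: Sequence[int], table: DiscreteFeatureSet,
                    criterion: Criterion = "difference",
                    _cache: _MiCache | None = None) -> float:
    cache = _cache or _MiCache(table)
    d = relevance(s, table, cache)
    r = redundancy(s, table, cache)
    if criterion == "difference":
        return d - r
    return d / max(r, _EPS_R)


def mrmr_select(
    table: DiscreteFeatureSet, k: int, criterion: Criterion = "difference"
) -> MrmrResult:
    """Greedy forward mRMR selection of k features.

    The first feature maximizes I(x_i; c); each later step adds the
    candidate maximizing the criterion of the augmented set.  Ties break
    toward the lowest feature index.
    """
    if not 1 <= k <= table.n_features:
        raise ValueError(f"k={k} out of range 1..{table.n_features}")
    if criterion not in ("difference", "quotient"):
        raise ValueError(f"unknown criterion {criterion!r}")
    cache = _MiCache(table)
    selected: list[int] = []
    scores: list[float] = []
    rel: list[float] = []
    red: list[float] = []
    remaining = list(range(table.n_features))

    first = max(remaining, key=lambda i: (cache.feature_class(i), -i))
    selected.append(first)
    remaining.remove(first)
    rel.append(relevance(selected, table, cache))
    red.append(redundancy(selected, table, cache))
    scores.append(cache.feature_class(first))

    while len(selected) < k:
        best_i, best_val = None, -np.inf
        for i in remaining:
            val = criterion_value(selected + [i], table, criterion, cache)
            if val > best_val + 1e-15:
                best_i, best_val = i, val
        assert best_i is not None
        selected.append(best_i)
        remaining.remove(best_i)
        rel.append(relevance(selected, table, cache))
        red.append(redundancy(selected, table, cache))
        scores.append(best_val)
    return MrmrResult(selected, scores, rel, red, criterion)


def discretize_table(
    values: np.ndarray,
    y: np.ndarray,
    thresholds: list[tuple[float, float]] | None = None,
) -> tuple[DiscreteFeatureSet, list[tuple[float, float]]]:
    """Discretize a real feature matrix column-wise.

    When ``thresholds`` (per-column (mu - sigma, mu + sigma) pairs fitted on
    training data) are given they are applied as-is, so a test table is
    coded on the training scale without leakage.
    """
    values = np.asarray(values, dtype=np.float64)
    cols = np.empty(values.shape, dtype=np.int64)
    fitted: list[tuple[float, float]] = []
    for j in range(values.shape[1]):
        col = values[:, j]
        if thresholds is None:
            mu, sigma = col.mean(), col.std()
            lo, hi = mu - sigma, mu + sigma
        else:
            lo, hi = thresholds[j]
        if hi <= lo:
            cols[:, j] = 0
        else:
            c = np.ones(len(col), dtype=np.int64)
            c[col < lo] = 0
            c[col > hi] = 2
            cols[:, j] = c
        fitted.append((lo, hi))
    return DiscreteFeatureSet(cols, np.asarray(y)), fitted


def select_features(
    values: np.ndarray,
    y: np.ndarray,
    k: int,
    criterion: Criterion = "difference",
) -> MrmrResult:
    """Discretize a real-valued feature matrix and run greedy mRMR."""
    table, _ = discretize_table(values, y)
    return mrmr_select(table, k, criterion)
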