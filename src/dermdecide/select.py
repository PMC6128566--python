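"""ReliefF feature ranking and the cumulative-feature-count sweep.

ReliefF scores each feature by how well it separates nearest neighbours of
opposite classes: for every instance the k nearest same-class "hits" and k
nearest other-class "misses" are found (Manhattan distance on
range-normalised features) and each feature's weight is increased by its
mean normalised difference to the misses and decreased by the difference to
the hits.  Every instance is visited exactly once, so the ranking is
deterministic.  Weights lie in [-1, 1]; a feature that is constant across
the table scores exactly 0.

The sweep plots classification performance (mean of cross-validated
sensitivity and specificity) against the number of top-ranked features
used, and reports the smallest count within a stated tolerance of the
curve's maximum — the plateau where extra features stop adding class
information.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .errors import InvalidInputError
from .io import FeatureTable

__all__ = ["RankedFeatures", "relieff_rank", "sweep_feature_count", "SweepResult"]


@dataclass
class RankedFeatures:
    """A permutation of feature indices sorted by non-increasing ReliefF
    weight (ties broken by ascending original index)."""

    order: np.ndarray
    weights: np.ndarray

    def top(self, n: int) -> np.ndarray:
        if not 1 <= n <= len(self.order):
            raise InvalidInputError(f"n must be in 1..{len(self.order)}, got {n}")
        return self.order[:n]


def relieff_rank(table: FeatureTable, k_neighbors: int = 10) -> RankedFeatures:
    """Rank all features of a labelled table with ReliefF.

    Every instance serves as a query (exhaustive iteration).  With two
    classes the hit/miss prior weighting reduces to 1, so the update is

        W_f += mean_f(diff to k misses) - mean_f(diff to k hits)

    accumulated over instances and divided by the instance count, keeping
    each weight in [-1, 1].  Requires every class to have more than
    ``k_neighbors`` members.
    """
    X, y = table.X, table.y
    table.require_both_classes()
    p, q = X.shape
    for cls in np.unique(y):
        if np.sum(y == cls) <= k_neighbors:
            raise InvalidInputError(
                f"class {cls} has {np.sum(y == cls)} members; "
                f"need more than k={k_neighbors}"
            )

    rng_span = X.max(axis=0) - X.min(axis=0)
    nonconstant = rng_span > 0
    Z = np.zeros_like(X)
    Z[:, nonconstant] = (X[:, nonconstant] - X.min(axis=0)[nonconstant]) / \
        rng_span[nonconstant]

    weights = np.zeros(q)
    for i in range(p):
        diffs = np.abs(Z - Z[i])          # p x q normalised differences
        dist = diffs.sum(axis=1)          # Manhattan distances to instance i
        same = y == y[i]
        hit_pool = np.flatnonzero(same)
        hit_pool = hit_pool[hit_pool != i]
        miss_pool = np.flatnonzero(~same)
        hits = hit_pool[np.argsort(dist[hit_pool], kind="stable")[:k_neighbors]]
        misses = miss_pool[np.argsort(dist[miss_pool], kind="stable")[:k_neighbors]]
        weights += diffs[misses].mean(axis=0) - diffs[hits].mean(axis=0)
    weights /= p

    order = np.argsort(-weights, kind="stable")
    return RankedFeatures(order=order, weights=weights)


@dataclass
class SweepResult:
    """Performance as a function of the cumulative top-feature count."""

    n_values: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    performance: np.ndarray       # mean of sensitivity and specificity
    error: np.ndarray
    plateau_n: int                # smallest n within tolerance of the maximum
    plateau_tol: float


def sweep_feature_count(table: FeatureTable, ranked: RankedFeatures,
                        clf_config=None, n_values=None, folds: int = 10,
                        seed: int = 0, plateau_tol: float = 0.005) -> SweepResult:
    """Cross-validated performance of the classifier on the top-n ranked
    features, for each n in *n_values*.

    The ranking is taken as given (computed once on the full table, as when
    reading a performance-vs-feature-count curve); the classifier is refit
    per fold.  Performance is the mean of sensitivity and specificity.
    """
    from .classify import SvmConfig, make_classifier  # deferred: avoid cycle

    if n_values is None:
        n_values = np.arange(1, min(201, table.n_features + 1))
    n_values = np.asarray(list(n_values), dtype=int)
    if n_values.size == 0:
        raise InvalidInputError("n_values must be non-empty")
    if n_values.max() > table.n_features or n_values.min() < 1:
        raise InvalidInputError(
            f"n_values must lie in 1..{table.n_features}"
        )
    clf_config = clf_config or SvmConfig()
    table.require_both_classes()

    X, y = table.X, table.y
    sens, spec, err = [], [], []
    splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    split_sets = list(splitter.split(X, y))
    for n in n_values:
        cols = ranked.top(int(n))
        tp = fp = tn = fn = 0
        for tr, te in split_sets:
            clf = make_classifier(clf_config, seed=seed)
            clf.fit(X[np.ix_(tr, cols)], y[tr])
            pred = clf.predict(X[np.ix_(te, cols)])
            tp += np.sum((pred == 1) & (y[te] == 1))
            fp += np.sum((pred == 1) & (y[te] == 0))
            tn += np.sum((pred == 0) & (y[te] == 0))
            fn += np.sum((pred == 0) & (y[te] == 1))
        sens.append(tp / max(tp + fn, 1))
        spec.append(tn / max(tn + fp, 1))
        err.append((fp + fn) / len(y))
    sens, spec, err = map(np.asarray, (sens, spec, err))
    perf = (sens + spec) / 2.0
    plateau_idx = np.flatnonzero(perf >= perf.max() - plateau_tol)[0]
    return SweepResult(n_values=n_values, sensitivity=sens, specificity=spec,
                       performance=perf, error=err,
                       plateau_n=int(n_values[plateau_idx]),
                       plateau_tol=plateau_tol)
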