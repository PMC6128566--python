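"""PCA feature extraction by SVD with a strict train/test contract.

The training matrix X (p samples x q features) is standardised column-wise
to zero mean and unit variance (sample standard deviation, n-1) and
factorised as X = W D V^T; the columns of V are the eigenvectors of X^T X
and the squared singular values divided by (p-1) are the variances of the
principal components.  Scores are PC_train = X V.  Test data — down to a
single 1 x q lesion vector — are standardised with the TRAINING mean and
standard deviation and projected onto the same V; the model is never refit
on test data.

Each column of V is sign-fixed so that its largest-magnitude entry is
positive, making the decomposition deterministic across platforms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError
from .io import FeatureTable

__all__ = ["PcaModel", "fit_pca", "transform", "eigenvalue_curve"]


@dataclass
class PcaModel:
    """Training statistics and loadings of a fitted PCA.

    ``V`` has shape (n retained features) x r with orthonormal columns,
    r = min(p, q); ``retained`` indexes the non-constant training columns
    the model operates on (all columns, normally).
    """

    train_mean: np.ndarray
    train_std: np.ndarray
    V: np.ndarray
    singular_values: np.ndarray
    n_samples: int
    n_features_in: int
    retained: np.ndarray

    @property
    def n_components_max(self) -> int:
        return self.V.shape[1]


def _as_matrix(train) -> np.ndarray:
    X = train.X if isinstance(train, FeatureTable) else np.asarray(train, dtype=float)
    if X.ndim != 2:
        raise InvalidInputError("training data must be a 2-D matrix")
    return X


def fit_pca(train, strict: bool = False) -> PcaModel:
    """Fit PCA on a training table (or raw matrix).

    Constant columns cannot be standardised; with ``strict`` they raise,
    otherwise they are dropped with a warning and ignored by
    :func:`transform`.
    """
    X = _as_matrix(train)
    p, q = X.shape
    if p < 2:
        raise InvalidInputError("need at least 2 training samples")
    mean = X.mean(axis=0)
    std = X.std(axis=0, ddof=1)
    constant = std == 0
    if constant.any():
        if strict:
            raise InvalidInputError(
                f"{constant.sum()} constant feature column(s); cannot standardise"
            )
        warnings.warn(f"dropping {constant.sum()} constant feature column(s)",
                      stacklevel=2)
    retained = np.flatnonzero(~constant)
    Z = (X[:, retained] - mean[retained]) / std[retained]
    _, s, Vt = np.linalg.svd(Z, full_matrices=False)
    V = Vt.T
    # deterministic sign: largest-|.| entry of each loading column positive
    flip = V[np.abs(V).argmax(axis=0), np.arange(V.shape[1])] < 0
    V[:, flip] *= -1.0
    return PcaModel(train_mean=mean, train_std=std, V=V, singular_values=s,
                    n_samples=p, n_features_in=q, retained=retained)


def transform(model: PcaModel, Y: np.ndarray, n_components: int | None = None) -> np.ndarray:
    """Project r x q test data (a single lesion being the r=1 case) into the
    training PC basis, keeping the first *n_components* columns.

    Standardisation uses the training mean and standard deviation only.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[1] != model.n_features_in:
        raise InvalidInputError(
            f"expected {model.n_features_in} columns, got {Y.shape[1]}"
        )
    n = model.n_components_max if n_components is None else int(n_components)
    if not 1 <= n <= model.n_components_max:
        raise InvalidInputError(
            f"n_components must be in 1..{model.n_components_max}, got {n}"
        )
    r = model.retained
    Z = (Y[:, r] - model.train_mean[r]) / model.train_std[r]
    return Z @ model.V[:, :n]


def eigenvalue_curve(model: PcaModel) -> np.ndarray:
    """Variances of the principal components, d_i^2 / (p-1), non-increasing,
    zero-padded to the feature count (a rank-deficient table has only p-1
    non-trivial components)."""
    lam = model.singular_values ** 2 / (model.n_samples - 1)
    pad = len(model.retained) - lam.size
    if pad > 0:
        lam = np.concatenate([lam, np.zeros(pad)])
    return lam
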