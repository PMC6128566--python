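"""The three classifiers compared for the excise / do-not-excise decision.

The primary model is a soft-margin SVM with the Gaussian radial basis
kernel K(x, x') = exp(-gamma * ||x - x'||^2) (gamma = 1/sigma in the usual
scale parametrisation) and Platt-scaled probabilistic output; random
forests and penalised logistic regression are provided for comparison.
The positive class is always "excise" (label 1) and the decision rule is
P(excise) >= threshold, so a probability exactly at the cutoff maps to
excision — the clinically conservative direction.

A :class:`TrainedModel` optionally carries the full preprocessing chain
(ReliefF-ranked feature indices and a fitted PCA), in which case it accepts
native 1152-column feature vectors and applies selection and extraction
before classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .errors import InvalidInputError
from .extract import PcaModel, fit_pca, transform
from .io import FeatureTable, PipelineConfig

__all__ = [
    "SvmConfig", "RfConfig", "LrConfig", "TrainedModel",
    "make_classifier", "train_svm", "train_rf", "train_lr",
    "train_pipeline", "predict",
]


@dataclass
class SvmConfig:
    """C trades margin width against training error; gamma scales the RBF
    kernel; the cutoff turns the Platt probability into a decision."""

    C: float = 30.0
    gamma: float = 0.007
    probability_threshold: float = 0.5

    def __post_init__(self):
        if self.C <= 0 or self.gamma <= 0:
            raise InvalidInputError("C and gamma must be positive")
        if not 0 < self.probability_threshold <= 1:
            raise InvalidInputError("probability_threshold must lie in (0, 1]")


@dataclass
class RfConfig:
    n_trees: int = 200
    min_leaf_size: int = 1
    probability_threshold: float = 0.5

    def __post_init__(self):
        if self.n_trees < 1 or self.min_leaf_size < 1:
            raise InvalidInputError("n_trees and min_leaf_size must be >= 1")


@dataclass
class LrConfig:
    """``reg_param`` is the penalty strength lambda multiplying the L1/L2
    penalty term (larger = more shrinkage)."""

    penalty: str = "L2"
    reg_param: float = 0.1
    probability_threshold: float = 0.5

    def __post_init__(self):
        if self.penalty.upper() not in ("L1", "L2"):
            raise InvalidInputError("penalty must be 'L1' or 'L2'")
        if self.reg_param <= 0:
            raise InvalidInputError("reg_param must be positive")


@dataclass
class TrainedModel:
    """A fitted classifier plus (optionally) its preprocessing chain."""

    algorithm: str
    estimator: object
    threshold: float = 0.5
    ranked_indices: np.ndarray | None = None   # ReliefF order, best first
    top_n: int | None = None
    pca: PcaModel | None = None
    n_components: int | None = None
    meta: dict = field(default_factory=dict)

    def chain_transform(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.ranked_indices is not None and self.top_n is not None:
            X = X[:, self.ranked_indices[: self.top_n]]
        if self.pca is not None:
            X = transform(self.pca, X, self.n_components)
        return X


def make_classifier(config, seed: int = 0):
    """Instantiate the scikit-learn estimator behind a config object."""
    if isinstance(config, SvmConfig):
        # Platt sigmoid calibration by internal 3-fold CV with a fixed seed;
        # ensemble=False keeps a single SVC fitted on the full training set
        svc = SVC(C=config.C, gamma=config.gamma, kernel="rbf")
        return CalibratedClassifierCV(
            svc, method="sigmoid", ensemble=False,
            cv=StratifiedKFold(3, shuffle=True, random_state=seed))
    if isinstance(config, RfConfig):
        return RandomForestClassifier(n_estimators=config.n_trees,
                                      min_samples_leaf=config.min_leaf_size,
                                      random_state=seed)
    if isinstance(config, LrConfig):
        return LogisticRegression(
            l1_ratio=1.0 if config.penalty.upper() == "L1" else 0.0,
            C=1.0 / config.reg_param, solver="liblinear", max_iter=2000)
    raise InvalidInputError(f"unknown classifier config {type(config).__name__}")


def _check_xy(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y)
    if X.shape[0] != y.shape[0]:
        raise InvalidInputError("X and y have different sample counts")
    if len(np.unique(y)) < 2:
        raise InvalidInputError("both classes must be present in training data")
    return X, y


def _train(X, y, config, seed: int, algorithm: str) -> TrainedModel:
    X, y = _check_xy(X, y)
    est = make_classifier(config, seed=seed)
    est.fit(X, y)
    return TrainedModel(algorithm=algorithm, estimator=est,
                        threshold=config.probability_threshold)


def train_svm(X, y, config: SvmConfig | None = None, seed: int = 0) -> TrainedModel:
    """Fit the RBF-SVM.  Platt scaling (an internal sigmoid fit on held-out
    decision values) provides the class probabilities; the fixed seed makes
    the calibration deterministic."""
    return _train(X, y, config or SvmConfig(), seed, "svm")


def train_rf(X, y, config: RfConfig | None = None, seed: int = 0) -> TrainedModel:
    """Fit a random forest; probabilities are tree-vote fractions."""
    return _train(X, y, config or RfConfig(), seed, "rf")


def train_lr(X, y, config: LrConfig | None = None, seed: int = 0) -> TrainedModel:
    """Fit penalised logistic regression; the probability is the logistic
    of the linear score."""
    return _train(X, y, config or LrConfig(), seed, "lr")


def _config_from_pipeline(cfg: PipelineConfig):
    if cfg.algorithm == "svm":
        return SvmConfig(C=cfg.C, gamma=cfg.gamma,
                         probability_threshold=cfg.probability_threshold)
    if cfg.algorithm == "rf":
        return RfConfig(n_trees=cfg.n_trees, min_leaf_size=cfg.min_leaf_size,
                        probability_threshold=cfg.probability_threshold)
    return LrConfig(penalty=cfg.lr_penalty, reg_param=cfg.lr_reg_param,
                    probability_threshold=cfg.probability_threshold)


def train_pipeline(table: FeatureTable, cfg: PipelineConfig | None = None) -> TrainedModel:
    """Fit the full chain on a native feature table: ReliefF ranking ->
    top-n selection -> PCA -> classifier.  The returned model consumes
    native q-column vectors."""
    from .select import relieff_rank  # deferred: avoid import cycle

    cfg = cfg or PipelineConfig()
    table.require_both_classes()
    ranked = relieff_rank(table, k_neighbors=cfg.relieff_k)
    top_n = min(cfg.top_n, table.n_features)
    cols = ranked.order[:top_n]
    pca = fit_pca(table.X[:, cols])
    n_comp = min(cfg.n_components, pca.n_components_max)
    scores = transform(pca, table.X[:, cols], n_comp)
    model = _train(scores, table.y, _config_from_pipeline(cfg), cfg.seed, cfg.algorithm)
    model.ranked_indices = ranked.order
    model.top_n = top_n
    model.pca = pca
    model.n_components = n_comp
    model.meta["relieff_weights"] = ranked.weights
    return model


def predict(model: TrainedModel, X: np.ndarray,
            threshold: float | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Probabilities of the excise class and the binary decisions.

    Applies the model's preprocessing chain if it has one; the decision is
    P(excise) >= threshold (the model's stored cutoff by default).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    expected = (model.ranked_indices.shape[0]
                if model.ranked_indices is not None
                else getattr(model.estimator, "n_features_in_", X.shape[1]))
    if X.shape[1] != expected:
        raise InvalidInputError(f"expected {expected} feature columns, got {X.shape[1]}")
    Z = model.chain_transform(X)
    classes = list(model.estimator.classes_)
    probs = model.estimator.predict_proba(Z)[:, classes.index(1)]
    thr = model.threshold if threshold is None else threshold
    return probs, probs >= thr
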