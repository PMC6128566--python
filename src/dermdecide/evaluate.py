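"""Cross-validated model accuracy, ROC analysis and the diagnostic odds ratio.

Repeated stratified k-fold cross-validation with the whole preprocessing
chain — ReliefF ranking and PCA — refit inside every training fold, so no
information from a held-out lesion ever reaches the model that predicts it.
A ``global_selection`` switch reproduces the optimistic alternative in
which ranking and extraction are computed once on the full table before
folding.  Leave-one-out (folds == sample count) is deterministic and runs
exactly once, with sensitivity and specificity pooled over the held-out
predictions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn import metrics as _skm
from sklearn.model_selection import StratifiedKFold, KFold

from .classify import TrainedModel, predict, train_pipeline, _train, \
    _config_from_pipeline
from .errors import InvalidInputError
from .extract import fit_pca, transform
from .io import FeatureTable, PipelineConfig

__all__ = ["CvResult", "RocCurve", "cross_validate", "roc_curve",
           "diagnostic_odds_ratio", "reproduce_operating_point"]


@dataclass
class CvResult:
    """Per-repeat confusion counts and metrics, plus their means."""

    folds: int
    repeats: int
    seed: int
    tp: np.ndarray
    fp: np.ndarray
    tn: np.ndarray
    fn: np.ndarray
    error: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    probabilities: np.ndarray | None = None   # pooled, last repeat
    labels: np.ndarray | None = None

    @property
    def mean_error(self) -> float:
        return float(self.error.mean())

    @property
    def mean_sensitivity(self) -> float:
        return float(self.sensitivity.mean())

    @property
    def mean_specificity(self) -> float:
        return float(self.specificity.mean())

    def summary(self) -> dict:
        return {
            "folds": self.folds, "repeats": self.repeats, "seed": self.seed,
            "mean_error": self.mean_error,
            "mean_sensitivity": self.mean_sensitivity,
            "mean_specificity": self.mean_specificity,
        }


def _fit_fold(table: FeatureTable, tr: np.ndarray, cfg: PipelineConfig) -> TrainedModel:
    sub = FeatureTable(table.X[tr], table.y[tr])
    return train_pipeline(sub, cfg)


def cross_validate(table: FeatureTable, cfg: PipelineConfig | None = None,
                   folds: int | None = None, repeats: int | None = None,
                   seed: int | None = None) -> CvResult:
    """Repeated cross-validation of the full pipeline on a native table.

    Fold assignment is stratified (class ratios preserved in every fold)
    and reseeded per repeat from the base seed, so a fixed seed makes the
    whole procedure reproducible.  ``folds == n_samples`` selects
    leave-one-out, which has a unique fold structure and therefore runs
    once regardless of ``repeats``.
    """
    cfg = cfg or PipelineConfig()
    folds = cfg.folds if folds is None else folds
    repeats = cfg.repeats if repeats is None else repeats
    seed = cfg.seed if seed is None else seed
    table.require_both_classes()
    p = table.n_samples
    if not 2 <= folds <= p:
        raise InvalidInputError(f"folds must be in 2..{p}, got {folds}")
    loo = folds == p
    if loo:
        repeats = 1

    counts = {k: [] for k in ("tp", "fp", "tn", "fn")}
    probs_last = labels_last = None
    for rep in range(repeats):
        if loo:
            splits = list(KFold(n_splits=p).split(table.X))
        elif cfg.stratify:
            splits = list(StratifiedKFold(n_splits=folds, shuffle=True,
                                          random_state=seed + rep)
                          .split(table.X, table.y))
        else:
            # plain random folds can strand a class; refold with a new seed
            for attempt in range(20):
                splits = list(KFold(n_splits=folds, shuffle=True,
                                    random_state=seed + rep + 1000 * attempt)
                              .split(table.X))
                if all(len(np.unique(table.y[tr])) == 2 for tr, _ in splits):
                    if attempt:
                        warnings.warn("refolded with a new seed: a fold "
                                      "contained a single class", stacklevel=2)
                    break
            else:
                raise InvalidInputError("could not build two-class folds")
        probs = np.zeros(p)
        pred = np.zeros(p, dtype=int)
        if cfg.global_selection:
            model = train_pipeline(table, cfg)
            order, top_n, n_comp = model.ranked_indices, model.top_n, model.n_components
        for tr, te in splits:
            if len(np.unique(table.y[tr])) < 2:
                raise InvalidInputError(
                    "a training fold contains one class only; use fewer folds"
                )
            if cfg.global_selection:
                cols = order[:top_n]
                pca = fit_pca(table.X[np.ix_(tr, cols)])
                n = min(n_comp, pca.n_components_max)
                fold_model = _train(transform(pca, table.X[np.ix_(tr, cols)], n),
                                    table.y[tr], _config_from_pipeline(cfg),
                                    cfg.seed, cfg.algorithm)
                Zte = transform(pca, table.X[np.ix_(te, cols)], n)
                pr = fold_model.estimator.predict_proba(Zte)
                pr = pr[:, list(fold_model.estimator.classes_).index(1)]
                probs[te] = pr
                pred[te] = (pr >= cfg.probability_threshold).astype(int)
            else:
                fold_model = _fit_fold(table, tr, cfg)
                pr, dec = predict(fold_model, table.X[te])
                probs[te], pred[te] = pr, dec.astype(int)
        y = table.y
        counts["tp"].append(np.sum((pred == 1) & (y == 1)))
        counts["fp"].append(np.sum((pred == 1) & (y == 0)))
        counts["tn"].append(np.sum((pred == 0) & (y == 0)))
        counts["fn"].append(np.sum((pred == 0) & (y == 1)))
        probs_last, labels_last = probs, y.copy()

    tp, fp, tn, fn = (np.asarray(counts[k]) for k in ("tp", "fp", "tn", "fn"))
    return CvResult(
        folds=folds, repeats=repeats, seed=seed, tp=tp, fp=fp, tn=tn, fn=fn,
        error=(fp + fn) / p,
        sensitivity=tp / np.maximum(tp + fn, 1),
        specificity=tn / np.maximum(tn + fp, 1),
        probabilities=probs_last, labels=labels_last,
    )


@dataclass
class RocCurve:
    """A receiver-operating-characteristic curve with trapezoidal AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def roc_curve(probabilities: np.ndarray, labels: np.ndarray) -> RocCurve:
    """Sweep the probability cutoff over the observed values and trace
    (FPR, TPR); starts at (0,0), ends at (1,1)."""
    probabilities = np.asarray(probabilities, dtype=float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise InvalidInputError("ROC needs both classes present")
    fpr, tpr, thr = _skm.roc_curve(labels, probabilities, pos_label=1)
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thr, auc=auc)


def diagnostic_odds_ratio(sensitivity: float, specificity: float) -> float:
    """DOR = (sens * spec) / ((1 - sens) * (1 - spec)).

    A single-number summary of a binary test; 1 means uninformative.
    Boundary values give an infinite ratio and are rejected explicitly.
    """
    s, c = float(sensitivity), float(specificity)
    if not (0.0 < s < 1.0 and 0.0 < c < 1.0):
        raise InvalidInputError(
            "diagnostic odds ratio is infinite/undefined at boundary "
            "sensitivity or specificity; inputs must lie strictly in (0,1)"
        )
    return (s * c) / ((1.0 - s) * (1.0 - c))


def reproduce_operating_point(excision_csv, noexcision_csv,
                              cfg: PipelineConfig | None = None,
                              repeats: int = 10) -> dict:
    """Run the reference analysis on a pair of per-class feature CSVs:
    ReliefF top-125 -> 22 PCs -> RBF-SVM (C=30, gamma=0.007), 10-fold CV
    (repeated) and leave-one-out CV, under both the leakage-free and the
    global-selection protocol.

    Returns a dict with both protocols' mean sensitivity/specificity/error
    and the LOO error.
    """
    from .io import load_table

    cfg = cfg or PipelineConfig()
    table = load_table(excision_csv, noexcision_csv)
    out: dict = {"n_excision": int(table.y.sum()),
                 "n_noexcision": int((1 - table.y).sum())}
    for label, global_sel in (("fold_refit", False), ("global_selection", True)):
        c = PipelineConfig(**{**cfg.__dict__, "global_selection": global_sel})
        cv10 = cross_validate(table, c, folds=10, repeats=repeats)
        loo = cross_validate(table, c, folds=table.n_samples)
        out[label] = {
            "cv10_sensitivity": cv10.mean_sensitivity,
            "cv10_specificity": cv10.mean_specificity,
            "cv10_error": cv10.mean_error,
            "loo_error": loo.mean_error,
        }
    return out
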