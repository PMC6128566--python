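import numpy as np
import pytest

from dermdecide.classify import (LrConfig, RfConfig, SvmConfig, TrainedModel,
                                 predict, train_lr, train_pipeline, train_rf,
                                 train_svm)
from dermdecide.errors import InvalidInputError
from dermdecide.io import FeatureTable, PipelineConfig


def _blobs(n=40, sep=4.0, seed=0):
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(-sep / 2, 1, (n // 2, 2)),
                   rng.normal(sep / 2, 1, (n // 2, 2))])
    y = np.repeat([0, 1], n // 2)
    return X, y


# ---------------------------------------------------------------------------
# SVM

def test_svm_separates_blobs_with_calibrated_probabilities():
    X, y = _blobs(sep=8.0)
    model = train_svm(X, y, SvmConfig(C=30, gamma=0.5))
    probs, dec = predict(model, X)
    assert np.mean(dec == y) == 1.0
    assert probs.min() >= 0.0 and probs.max() <= 1.0
    # complementary class probability
    both = model.estimator.predict_proba(X)
    assert np.allclose(both.sum(axis=1), 1.0)


def test_svm_single_class_rejected():
    with pytest.raises(InvalidInputError):
        train_svm(np.zeros((10, 2)), np.zeros(10))


def test_increasing_C_weakly_decreases_training_error():
    X, y = _blobs(n=60, sep=1.5, seed=2)
    errs = []
    for C in (0.1, 1.0, 10.0, 100.0):
        model = train_svm(X, y, SvmConfig(C=C, gamma=0.5))
        inner = model.estimator.calibrated_classifiers_[0].estimator
        errs.append(np.mean(inner.predict(X) != y))
    assert all(a >= b - 1e-12 for a, b in zip(errs, errs[1:]))


def test_decision_function_depends_only_on_support_vectors():
    """Dropping a training point that is not a support vector must leave
    the (uncalibrated) decision function unchanged."""
    X, y = _blobs(n=60, sep=6.0, seed=4)
    m_full = train_svm(X, y, SvmConfig(C=30, gamma=0.2))
    svc = m_full.estimator.calibrated_classifiers_[0].estimator
    support = set(svc.support_)
    drop = next(i for i in range(len(y)) if i not in support)
    keep = np.arange(len(y)) != drop
    m_red = train_svm(X[keep], y[keep], SvmConfig(C=30, gamma=0.2))
    svc_red = m_red.estimator.calibrated_classifiers_[0].estimator
    grid = np.random.default_rng(0).normal(0, 3, (50, 2))
    assert np.allclose(svc.decision_function(grid),
                       svc_red.decision_function(grid), atol=1e-9)


# ---------------------------------------------------------------------------
# RF

def test_full_depth_forest_memorises_training_set():
    """With leaf size 1 the bagged full-depth trees jointly memorise a
    conflict-free training set (single trees see only a bootstrap sample)."""
    X, y = _blobs(n=30, sep=2.0, seed=1)
    model = train_rf(X, y, RfConfig(n_trees=100, min_leaf_size=1))
    _, dec = predict(model, X)
    assert np.mean(dec == y) == 1.0


def test_rf_probabilities_are_vote_fractions():
    X, y = _blobs(n=40, sep=1.0, seed=3)
    model = train_rf(X, y, RfConfig(n_trees=10, min_leaf_size=5))
    probs, _ = predict(model, X)
    # leaves may be impure with min_leaf_size>1; per-tree leaf proportions
    # still make every probability an average of 10 leaf fractions
    assert np.all((0 <= probs) & (probs <= 1))
    model1 = train_rf(X, y, RfConfig(n_trees=8, min_leaf_size=1))
    probs1, _ = predict(model1, X)
    votes = probs1 * 8
    assert np.allclose(votes, np.round(votes), atol=1e-9)


def test_rf_reproducible_and_recovers_planted_signal(small_table):
    table, _ = small_table
    m1 = train_rf(table.X, table.y, RfConfig(n_trees=100), seed=11)
    m2 = train_rf(table.X, table.y, RfConfig(n_trees=100), seed=11)
    p1, _ = predict(m1, table.X)
    p2, _ = predict(m2, table.X)
    assert np.array_equal(p1, p2)  # bit-reproducible under a fixed seed
    # out-of-bag error on a planted 5-informative table at effect size 2
    from sklearn.ensemble import RandomForestClassifier
    from dermdecide.synth import SyntheticTableSpec, make_feature_table
    big, _ = make_feature_table(SyntheticTableSpec(
        seed=5, n_pos=100, n_neg=100, q=30, n_informative=5, delta=2.0,
        block_size=6))
    rf = RandomForestClassifier(n_estimators=200, min_samples_leaf=1,
                                oob_score=True, random_state=0)
    rf.fit(big.X, big.y)
    assert 1.0 - rf.oob_score_ < 0.1


# ---------------------------------------------------------------------------
# LR

def test_lr_null_data_gives_chance_probabilities(rng):
    X = rng.standard_normal((200, 5))
    y = np.tile([0, 1], 100)
    model = train_lr(X, y, LrConfig(penalty="L2", reg_param=0.1))
    probs, _ = predict(model, X)
    assert abs(probs.mean() - 0.5) < 0.05
    # coefficients shrink toward zero as the penalty grows
    norms = []
    for lam in (0.01, 1.0, 100.0):
        m = train_lr(X, y, LrConfig(penalty="L2", reg_param=lam))
        norms.append(np.linalg.norm(m.estimator.coef_))
    assert norms[0] >= norms[1] >= norms[2]


def test_lr_l1_sparsity_keeps_informative_feature(rng):
    n = 200
    y = np.tile([0, 1], n // 2)
    X = rng.standard_normal((n, 6)) * 0.5
    X[:, 2] += 3.0 * y  # single strongly informative feature
    model = train_lr(X, y, LrConfig(penalty="L1", reg_param=5.0))
    coef = model.estimator.coef_.ravel()
    assert coef[2] != 0.0
    assert np.sum(np.abs(coef) > 1e-8) <= 2


def test_lr_probability_monotone_in_linear_score(rng):
    X = rng.standard_normal((100, 3))
    y = (X[:, 0] > 0).astype(int)
    model = train_lr(X, y)
    probs, _ = predict(model, X)
    scores = model.estimator.decision_function(X)
    order = np.argsort(scores)
    assert np.all(np.diff(probs[order]) >= -1e-12)


# ---------------------------------------------------------------------------
# predict contract

class _FixedProbEstimator:
    classes_ = np.array([0, 1])
    n_features_in_ = 1

    def __init__(self, probs):
        self._p = np.asarray(probs, dtype=float)

    def predict_proba(self, X):
        return np.column_stack([1 - self._p, self._p])


def test_threshold_boundary_maps_to_excise():
    model = TrainedModel(algorithm="svm",
                         estimator=_FixedProbEstimator([0.5, 0.49, 1.0]),
                         threshold=0.5)
    X = np.zeros((3, 1))
    _, dec = predict(model, X)
    assert dec.tolist() == [True, False, True]  # P == cutoff -> excise
    _, dec_strict = predict(model, X, threshold=1.0)
    assert dec_strict.tolist() == [False, False, True]


def test_predict_dimension_mismatch(small_table):
    table, _ = small_table
    model = train_svm(table.X, table.y, SvmConfig(C=10, gamma=0.05))
    with pytest.raises(InvalidInputError):
        predict(model, np.zeros((2, table.n_features + 1)))


def test_full_pipeline_model_consumes_native_vectors(small_table):
    table, _ = small_table
    cfg = PipelineConfig(top_n=10, n_components=5, relieff_k=5,
                         C=10, gamma=0.05)
    model = train_pipeline(table, cfg)
    probs, dec = predict(model, table.X)
    assert probs.shape == (table.n_samples,)
    assert np.mean(dec == table.y) > 0.9
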