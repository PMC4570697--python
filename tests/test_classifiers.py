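"""The three classifiers, the SVM grid search, and cross-validation."""
import numpy as np
import pandas as pd
import pytest
from sklearn.neighbors import KNeighborsClassifier

from synapred import (
    ClassifierSpec,
    cross_validate,
    grid_search_svm,
    predict_knn,
    predict_rf,
    predict_svm,
    score_all,
)
from synapred.classifiers import ConfigurationError, MODELS


def frame(arr, prefix="g"):
    arr = np.asarray(arr, dtype=float)
    return pd.DataFrame(arr, index=[f"{prefix}{i}" for i in range(len(arr))])


def test_knn_probability_is_positive_fraction_of_neighbors():
    # five training points on a line; query at 0 has neighbors 0,1,2 (k=3)
    X_train = frame([[0.0], [1.0], [2.0], [10.0], [11.0]])
    y = pd.Series([1, 0, 1, 0, 0], index=X_train.index)
    p = predict_knn(X_train, y, frame([[0.0]], "q"), k=3)
    assert p.iloc[0] == pytest.approx(2 / 3)


def test_knn_identity_query_with_k1_returns_label():
    X_train = frame([[0.0, 5.0], [3.0, 1.0]])
    y = pd.Series([1, 0], index=X_train.index)
    p = predict_knn(X_train, y, X_train, k=1)
    assert p.tolist() == [1.0, 0.0]


def test_knn_k_larger_than_training_is_an_error():
    X_train = frame([[0.0], [1.0]])
    y = pd.Series([1, 0], index=X_train.index)
    with pytest.raises(ConfigurationError):
        predict_knn(X_train, y, X_train, k=3)


def test_knn_matches_sklearn_on_random_fixture(rng):
    """Dual-route check: our stable-sort k-NN against sklearn's estimator on
    a 50-gene fixture (random floats: no distance ties)."""
    X_train = frame(rng.normal(size=(50, 24)))
    y = pd.Series(rng.integers(0, 2, size=50), index=X_train.index)
    X = frame(rng.normal(size=(30, 24)), "q")
    ours = predict_knn(X_train, y, X, k=7)
    oracle = KNeighborsClassifier(n_neighbors=7).fit(X_train, y)
    theirs = oracle.predict_proba(X)[:, list(oracle.classes_).index(1)]
    np.testing.assert_allclose(ours.to_numpy(), theirs)


def test_knn_probabilities_are_multiples_of_one_over_k(small_run):
    p = predict_knn(
        small_run.train_profiles,
        small_run.labels,
        small_run.profiles.iloc[:100],
        k=25,
    )
    np.testing.assert_allclose(p * 25, np.round(p * 25), atol=1e-9)


def test_rf_single_tree_votes_zero_or_one(rng):
    X_train = frame(rng.normal(size=(40, 5)))
    y = pd.Series(rng.integers(0, 2, size=40), index=X_train.index)
    p = predict_rf(X_train, y, frame(rng.normal(size=(20, 5)), "q"), n_trees=1, m_vars=2, seed=0)
    assert set(p.unique()) <= {0.0, 1.0}


def test_rf_is_order_invariant_and_seeded(rng):
    X_train = frame(rng.normal(size=(40, 5)))
    y = pd.Series(rng.integers(0, 2, size=40), index=X_train.index)
    X = frame(rng.normal(size=(20, 5)), "q")
    p1 = predict_rf(X_train, y, X, n_trees=50, m_vars=2, seed=3)
    p2 = predict_rf(X_train, y, X.iloc[::-1], n_trees=50, m_vars=2, seed=3)
    pd.testing.assert_series_equal(p1, p2.loc[p1.index])


def test_svm_wide_margin_duplicated_points(rng):
    """Two well-separated point clouds: the calibrated probability lands on
    the duplicate's side of 0.5 with a wide margin."""
    pos = np.tile([1.0, 1.0], (10, 1)) + rng.normal(0, 0.01, (10, 2))
    neg = np.tile([-1.0, -1.0], (10, 1)) + rng.normal(0, 0.01, (10, 2))
    X_train = frame(np.vstack([pos, neg]))
    y = pd.Series([1] * 10 + [0] * 10, index=X_train.index)
    p = predict_svm(X_train, y, frame([[1.0, 1.0], [-1.0, -1.0]], "q"), C=10.0, gamma=5.0)
    assert p.iloc[0] > 0.8 and p.iloc[1] < 0.2


def test_svm_invalid_parameters_rejected(small_run):
    with pytest.raises(ConfigurationError):
        predict_svm(small_run.train_profiles, small_run.labels, small_run.train_profiles, C=-1, gamma=0.1)


def test_grid_search_single_point_returned(noise_free_run):
    C, gamma, _ = grid_search_svm(
        noise_free_run.train_profiles, noise_free_run.labels,
        grid_c=(3.0,), grid_gamma=(0.01,), seed=0,
    )
    assert (C, gamma) == (3.0, 0.01)


def test_grid_search_ties_resolve_to_smaller_c_then_gamma(noise_free_run):
    """On separable noise-free data several grid points reach error 0; the
    smallest C (then gamma) must win."""
    C, gamma, err = grid_search_svm(
        noise_free_run.train_profiles, noise_free_run.labels,
        grid_c=(1.0, 5.0), grid_gamma=(0.05, 0.5), seed=0,
    )
    assert err == 0.0
    assert (C, gamma) == (1.0, 0.05)


def test_grid_search_empty_grid_is_an_error(small_run):
    with pytest.raises(ConfigurationError):
        grid_search_svm(small_run.train_profiles, small_run.labels, grid_c=(), grid_gamma=(0.1,))


@pytest.mark.parametrize("model", MODELS)
def test_noise_free_classes_are_perfectly_cross_validated(noise_free_run, model):
    """In the separable noise-free limit every model reaches zero CV error
    and AUC 1."""
    spec = ClassifierSpec(knn_k=5)
    report = cross_validate(model, noise_free_run.train_profiles, noise_free_run.labels, spec, seed=3)
    assert report.mean_error == 0.0
    assert report.auc == 1.0
    assert len(report.fold_errors) == 10


def test_permuted_labels_give_chance_auc(noise_free_run):
    aucs = []
    for rep in range(20):
        permuted = (
            noise_free_run.labels.sample(frac=1.0, random_state=rep)
            .set_axis(noise_free_run.labels.index)
        )
        aucs.append(
            cross_validate(
                "knn", noise_free_run.train_profiles, permuted,
                ClassifierSpec(knn_k=5), seed=rep,
            ).auc
        )
    assert abs(np.mean(aucs) - 0.5) < 0.1


def test_cross_validation_is_deterministic_given_seed(small_run):
    spec = ClassifierSpec(knn_k=5)
    a = cross_validate("knn", small_run.train_profiles, small_run.labels, spec, seed=9)
    b = cross_validate("knn", small_run.train_profiles, small_run.labels, spec, seed=9)
    assert a.fold_errors == b.fold_errors and a.auc == b.auc


def test_probability_table_schema_and_range(small_run):
    probs = score_all(
        small_run.train_profiles,
        small_run.labels,
        small_run.profiles.iloc[:50],
        ClassifierSpec(knn_k=5),
        seed=1,
    )
    assert list(probs.columns) == ["p_knn", "p_rf", "p_svm", "mean_p"]
    assert ((probs.to_numpy() >= 0) & (probs.to_numpy() <= 1)).all()
    assert len(probs) == 50
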