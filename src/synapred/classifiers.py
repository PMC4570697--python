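"""The three probabilistic classifiers, their tuning, and 10-fold cross-validation.

Each model estimates P(y = 1 | x) for a gene from its normalized 24-sample
profile x:

* k-NN: the fraction of positive labels among the k = 25 Euclidean nearest
  training profiles; distance ties are broken deterministically by gene id.
* Random forest: the fraction of the B = 500 trees (m = 4 candidate
  variables per split) voting positive.
* RBF-kernel SVM: Platt-calibrated class probabilities; cost C and kernel
  width gamma tuned by a cross-validated grid search (default grid spans
  the region around C = 2.2, gamma = 0.02).

A gene is called synaptic when its estimated probability strictly exceeds
the decision threshold (default 0.5).  Generalization error is estimated
by stratified 10-fold cross-validation; AUC is computed from the pooled
out-of-fold probabilities.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

MODELS = ("knn", "rf", "svm")
#: ProbabilityTable column per model
MODEL_COLUMNS = {"knn": "p_knn", "rf": "p_rf", "svm": "p_svm"}
DEFAULT_THRESHOLD = 0.5


class ConfigurationError(ValueError):
    pass


@dataclass
class ClassifierSpec:
    """Hyperparameters of the three models."""

    knn_k: int = 25
    rf_trees: int = 500
    rf_vars: int = 4
    svm_c: float = 2.2
    svm_gamma: float = 0.02
    svm_grid_c: tuple[float, ...] = (0.5, 1.0, 2.2, 5.0, 10.0)
    svm_grid_gamma: tuple[float, ...] = (0.005, 0.01, 0.02, 0.05, 0.1)

    def validate(self, n_features: int = 24) -> "ClassifierSpec":
        if self.knn_k < 1:
            raise ConfigurationError("knn_k must be >= 1")
        if self.rf_trees < 1:
            raise ConfigurationError("rf_trees must be >= 1")
        if not 1 <= self.rf_vars <= n_features:
            raise ConfigurationError(f"rf_vars must be in [1, {n_features}]")
        if self.svm_c <= 0 or self.svm_gamma <= 0:
            raise ConfigurationError("svm_c and svm_gamma must be > 0")
        return self


@dataclass
class CVReport:
    """Result of one model's 10-fold cross-validation."""

    model: str
    fold_errors: list[float]
    fold_aucs: list[float]
    mean_error: float
    auc: float  # pooled out-of-fold AUC
    seed: int
    params: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "fold_errors": self.fold_errors,
            "fold_aucs": self.fold_aucs,
            "mean_error": self.mean_error,
            "auc": self.auc,
            "seed": self.seed,
            "params": self.params,
        }


def _as_frame(X) -> pd.DataFrame:
    return X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, dtype=float))


def predict_knn(
    train_profiles: pd.DataFrame,
    train_labels: pd.Series,
    X: pd.DataFrame,
    k: int = 25,
) -> pd.Series:
    """k-NN probability: positive fraction among the k nearest training profiles.

    Training rows are ordered by gene id before a stable distance sort, so
    exact distance ties at the k-th rank resolve deterministically.
    """
    train_profiles = _as_frame(train_profiles).sort_index()
    train_labels = train_labels.loc[train_profiles.index]
    if k > len(train_profiles):
        raise ConfigurationError(
            f"k = {k} exceeds training-set size {len(train_profiles)}"
        )
    X = _as_frame(X)
    d = cdist(X.to_numpy(dtype=float), train_profiles.to_numpy(dtype=float))
    order = np.argsort(d, axis=1, kind="stable")[:, :k]
    y = train_labels.to_numpy(dtype=float)
    p = y[order].mean(axis=1)
    return pd.Series(p, index=X.index, name="p_knn")


def predict_rf(
    train_profiles: pd.DataFrame,
    train_labels: pd.Series,
    X: pd.DataFrame,
    n_trees: int = 500,
    m_vars: int = 4,
    seed: int = 0,
) -> pd.Series:
    """Random-forest probability: fraction of trees voting positive."""
    train_profiles = _as_frame(train_profiles).sort_index()
    train_labels = train_labels.loc[train_profiles.index]
    X = _as_frame(X)
    rf = RandomForestClassifier(
        n_estimators=n_trees,
        max_features=m_vars,
        random_state=int(seed),
        n_jobs=1,
    )
    rf.fit(train_profiles.to_numpy(dtype=float), train_labels.to_numpy(dtype=int))
    X_arr = X.to_numpy(dtype=float)
    votes = np.stack([tree.predict(X_arr) for tree in rf.estimators_])
    return pd.Series(votes.mean(axis=0), index=X.index, name="p_rf")


def predict_svm(
    train_profiles: pd.DataFrame,
    train_labels: pd.Series,
    X: pd.DataFrame,
    C: float = 2.2,
    gamma: float = 0.02,
    seed: int = 0,
) -> pd.Series:
    """RBF-SVM probability via a Platt sigmoid fitted on cross-validated decision values."""
    if C <= 0 or gamma <= 0:
        raise ConfigurationError("C and gamma must be > 0")
    train_profiles = _as_frame(train_profiles).sort_index()
    train_labels = train_labels.loc[train_profiles.index]
    X = _as_frame(X)
    clf = CalibratedClassifierCV(
        SVC(kernel="rbf", C=C, gamma=gamma), method="sigmoid", cv=5, ensemble=False
    )
    clf.fit(train_profiles.to_numpy(dtype=float), train_labels.to_numpy(dtype=int))
    pos = list(clf.classes_).index(1)
    p = clf.predict_proba(X.to_numpy(dtype=float))[:, pos]
    return pd.Series(p, index=X.index, name="p_svm")


def _predict(
    model: str,
    train_profiles: pd.DataFrame,
    train_labels: pd.Series,
    X: pd.DataFrame,
    spec: ClassifierSpec,
    seed: int,
) -> pd.Series:
    if model == "knn":
        return predict_knn(train_profiles, train_labels, X, k=spec.knn_k)
    if model == "rf":
        return predict_rf(
            train_profiles, train_labels, X,
            n_trees=spec.rf_trees, m_vars=spec.rf_vars, seed=seed,
        )
    if model == "svm":
        return predict_svm(
            train_profiles, train_labels, X,
            C=spec.svm_c, gamma=spec.svm_gamma, seed=seed,
        )
    raise ConfigurationError(f"unknown model {model!r}")


def grid_search_svm(
    train_profiles: pd.DataFrame,
    train_labels: pd.Series,
    grid_c: tuple[float, ...] | None = None,
    grid_gamma: tuple[float, ...] | None = None,
    folds: int = 10,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Pick (C, gamma) with the lowest mean cross-validated misclassification.

    Ties resolve to the smaller C, then the smaller gamma.  Returns
    (C*, gamma*, best mean error).
    """
    spec = ClassifierSpec()
    grid_c = tuple(grid_c) if grid_c is not None else spec.svm_grid_c
    grid_gamma = tuple(grid_gamma) if grid_gamma is not None else spec.svm_grid_gamma
    if not grid_c or not grid_gamma:
        raise ConfigurationError("SVM grid must be non-empty")
    X = _as_frame(train_profiles).sort_index()
    y = train_labels.loc[X.index].to_numpy(dtype=int)
    X_arr = X.to_numpy(dtype=float)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=int(seed))
    splits = list(skf.split(X_arr, y))
    best: tuple[float, float, float] | None = None
    for C, gamma in itertools.product(sorted(grid_c), sorted(grid_gamma)):
        errors = []
        for tr, te in splits:
            svm = SVC(kernel="rbf", C=C, gamma=gamma)
            svm.fit(X_arr[tr], y[tr])
            errors.append(float(np.mean(svm.predict(X_arr[te]) != y[te])))
        mean_err = float(np.mean(errors))
        if best is None or mean_err < best[2]:
            best = (C, gamma, mean_err)
    assert best is not None
    return best


def cross_validate(
    model: str,
    train_profiles: pd.DataFrame,
    train_labels: pd.Series,
    spec: ClassifierSpec | None = None,
    folds: int = 10,
    seed: int = 0,
    threshold: float = DEFAULT_THRESHOLD,
) -> CVReport:
    """Stratified k-fold cross-validation of one model.

    Mean error is the average per-fold misclassification rate under the
    strict > threshold decision rule; AUC is computed once from the pooled
    out-of-fold probabilities (per-fold AUCs are recorded as well).
    """
    spec = (spec or ClassifierSpec()).validate()
    X = _as_frame(train_profiles).sort_index()
    y = train_labels.loc[X.index]
    if len(X) < folds:
        raise ConfigurationError(f"training set smaller than {folds} folds")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=int(seed))
    y_arr = y.to_numpy(dtype=int)
    oof = np.full(len(X), np.nan)
    fold_errors, fold_aucs = [], []
    for tr, te in skf.split(X.to_numpy(dtype=float), y_arr):
        p = _predict(model, X.iloc[tr], y.iloc[tr], X.iloc[te], spec, seed)
        p_arr = p.to_numpy()
        oof[te] = p_arr
        pred = p_arr > threshold
        fold_errors.append(float(np.mean(pred != (y_arr[te] == 1))))
        if len(np.unique(y_arr[te])) == 2:
            fold_aucs.append(float(roc_auc_score(y_arr[te], p_arr)))
    assert not np.isnan(oof).any()
    params = {
        "knn": {"k": spec.knn_k},
        "rf": {"n_trees": spec.rf_trees, "m_vars": spec.rf_vars},
        "svm": {"C": spec.svm_c, "gamma": spec.svm_gamma},
    }[model]
    return CVReport(
        model=model,
        fold_errors=fold_errors,
        fold_aucs=fold_aucs,
        mean_error=float(np.mean(fold_errors)),
        auc=float(roc_auc_score(y_arr, oof)),
        seed=int(seed),
        params=params,
    )


def score_all(
    train_profiles: pd.DataFrame,
    train_labels: pd.Series,
    X: pd.DataFrame,
    spec: ClassifierSpec | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Fit all three models on the training set and score X.

    Returns the ProbabilityTable: one row per gene with columns
    p_knn, p_rf, p_svm and their mean.
    """
    spec = (spec or ClassifierSpec()).validate()
    table = pd.DataFrame(index=_as_frame(X).index)
    for model in MODELS:
        table[MODEL_COLUMNS[model]] = _predict(
            model, train_profiles, train_labels, X, spec, seed
        )
    table["mean_p"] = table[[MODEL_COLUMNS[m] for m in MODELS]].mean(axis=1)
    table.index.name = "gene_id"
    return table
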