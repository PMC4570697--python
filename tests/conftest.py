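"""Shared fixtures: scaled-down synthetic datasets and one full default-scale run."""
from __future__ import annotations

import dataclasses
from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest

from synapred import (
    ClassifierSpec,
    SyntheticConfig,
    build_training_set,
    cross_validate,
    generate_all,
    grid_search_svm,
    score_all,
)
from synapred.classifiers import MODELS
from synapred.preprocess import ALL_COLUMNS, filter_expressed, normalize


def make_matrix(rows: dict[str, list[float]]) -> pd.DataFrame:
    """Build a 30-column expression matrix from explicit per-gene values."""
    m = pd.DataFrame.from_dict(rows, orient="index", columns=list(ALL_COLUMNS))
    m.index.name = "gene_id"
    return m.astype(float)


SMALL = SyntheticConfig(
    n_synaptic=30,
    n_hidden_synaptic=40,
    n_nonsynaptic_cnslow=60,
    n_nonsynaptic_sexbias=10,
    n_background=400,
    n_adult_only=20,
    annot_terms=10,
    seed=11,
)


@pytest.fixture(scope="session")
def small_data():
    """A miniature synthetic study (30/70 training, ~500 classified genes)."""
    return generate_all(SMALL)


@pytest.fixture(scope="session")
def noise_free_data():
    """Noise-free miniature study: classes exactly separable by construction."""
    return generate_all(dataclasses.replace(SMALL, noise_sd=0.0))


def prepare(data):
    """Preprocess + training-set assembly for a generated dataset."""
    expressed = filter_expressed(data.expression)
    profiles = normalize(data.expression, expressed)
    training, classification = build_training_set(
        set(data.positives), data.expression, data.tissue, expressed
    )
    labels = training.labels()
    return SimpleNamespace(
        data=data,
        expressed=expressed,
        profiles=profiles,
        training=training,
        classification=classification,
        labels=labels,
        train_profiles=profiles.loc[labels.index],
    )


@pytest.fixture(scope="session")
def small_run(small_data):
    return prepare(small_data)


@pytest.fixture(scope="session")
def noise_free_run(noise_free_data):
    return prepare(noise_free_data)


@pytest.fixture(scope="session")
def default_run():
    """One full run at the default study conditions (92/397 training, ~12.8k
    classified genes): grid-searched SVM, 10-fold CV for the three models,
    probability table for the whole classification set."""
    run = prepare(generate_all(SyntheticConfig(seed=0)))
    c_star, gamma_star, _ = grid_search_svm(run.train_profiles, run.labels, seed=0)
    spec = dataclasses.replace(ClassifierSpec(), svm_c=c_star, svm_gamma=gamma_star)
    run.spec = spec
    run.cv = {
        m: cross_validate(m, run.train_profiles, run.labels, spec, seed=0)
        for m in MODELS
    }
    run.probs = score_all(
        run.train_profiles,
        run.labels,
        run.profiles.loc[sorted(run.classification)],
        spec,
        seed=0,
    )
    return run


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
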