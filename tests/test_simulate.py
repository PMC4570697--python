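"""Generator invariants: counts, planted signals, determinism."""
import dataclasses

import numpy as np
import pandas as pd
import pytest

from synapred import SyntheticConfig, generate_all, generate_expression, generate_homology
from synapred.enrichment import term_enrichment
from synapred.preprocess import ADULT_COLUMNS, STAGE_COLUMNS
from synapred.simulate import (
    ConfigurationError,
    PLANTED_TERM,
    PLANT_CNS_LOW,
    PLANT_SEX_BIAS,
)
from synapred.tissue_homology import random_list_null, synaptic_homolog_overlap

TINY = SyntheticConfig(
    n_synaptic=8,
    n_hidden_synaptic=6,
    n_nonsynaptic_cnslow=10,
    n_nonsynaptic_sexbias=5,
    n_background=60,
    n_adult_only=3,
    annot_terms=5,
    seed=7,
)


@pytest.mark.parametrize(
    "bad",
    [
        {"n_synaptic": -1},
        {"wave_high": 1.0, "trough_low": 2.0},
        {"noise_sd": -0.1},
        {"planted_term_frac": 1.5},
        {"blend_mixture": (0.5, 0.5, 0.5)},
    ],
)
def test_invalid_config_rejected(bad):
    with pytest.raises(ConfigurationError):
        dataclasses.replace(TINY, **bad).validate()


def test_noise_free_synaptic_profiles_equal_template():
    cfg = dataclasses.replace(TINY, noise_sd=0.0, wave_high=10.0, trough_low=1.0)
    matrix, truth = generate_expression(cfg)
    stage = matrix.loc[truth.synaptic, list(STAGE_COLUMNS)]
    assert (stage.iloc[:, 6:12] == 10.0).all().all()
    assert (stage.iloc[:, 18:24] == 10.0).all().all()
    assert (stage.iloc[:, :6] == 1.0).all().all()
    assert (stage.iloc[:, 12:18] == 1.0).all().all()


def test_class_counts_and_mutual_exclusivity():
    matrix, truth = generate_expression(TINY)
    counts = truth.table["planted"].value_counts()
    assert counts["curated_positive"] == TINY.n_synaptic
    assert counts["hidden_synaptic"] == TINY.n_hidden_synaptic
    assert counts[PLANT_CNS_LOW] == TINY.n_nonsynaptic_cnslow
    assert counts[PLANT_SEX_BIAS] == TINY.n_nonsynaptic_sexbias
    assert counts["background"] == TINY.n_background
    assert counts["adult_only"] == TINY.n_adult_only
    # every generated gene appears exactly once, with one class
    assert len(truth.table) == len(matrix) == counts.sum()
    assert not truth.table.index.duplicated().any()


def test_no_negative_fpkm_and_adult_only_structure():
    matrix, truth = generate_expression(TINY)
    assert (matrix.to_numpy() >= 0).all()
    adult_only = truth.genes("adult_only")
    stage = matrix.loc[adult_only, list(STAGE_COLUMNS)]
    adult = matrix.loc[adult_only, list(ADULT_COLUMNS)]
    assert (stage == 0).all().all()
    assert (adult > 0).any(axis=1).all()
    # exactly n_adult_only genes have an all-zero stage profile
    assert int((matrix[list(STAGE_COLUMNS)].sum(axis=1) == 0).sum()) == TINY.n_adult_only


def test_sex_bias_planting_is_extreme():
    matrix, truth = generate_expression(TINY)
    female = matrix[["A1f", "A2f", "A3f"]]
    male = matrix[["A1m", "A2m", "A3m"]]
    for gene in truth.genes(PLANT_SEX_BIAS):
        f, m = female.loc[gene], male.loc[gene]
        zero_one_sex = (f == 0).all() or (m == 0).all()
        high_other = (m > 25).any() if (f == 0).all() else (f > 25).any()
        assert zero_one_sex and high_other


def test_synaptic_mean_profile_peaks_in_both_waves(default_run):
    """The mean normalized synaptic profile has its two highest 6-sample
    windows exactly over the late-embryo and pupal synaptogenesis waves."""
    truth = default_run.data.truth
    mean_profile = default_run.profiles.loc[truth.synaptic].mean().to_numpy()
    window_means = [mean_profile[i * 6 : (i + 1) * 6].mean() for i in range(4)]
    assert set(np.argsort(window_means)[-2:]) == {1, 3}


def test_identical_config_and_seed_is_bit_identical():
    a, b = generate_all(TINY), generate_all(TINY)
    pd.testing.assert_frame_equal(a.expression, b.expression)
    pd.testing.assert_frame_equal(a.tissue, b.tissue)
    pd.testing.assert_frame_equal(a.truth.table, b.truth.table)
    assert a.gene_sets == b.gene_sets
    assert a.homology == b.homology and a.human_synaptic == b.human_synaptic


def test_different_seed_changes_output():
    a = generate_all(TINY)
    b = generate_all(dataclasses.replace(TINY, seed=8))
    assert not a.expression.equals(b.expression)


def test_tissue_table_cns_ratio_count_matches_planting(default_run):
    tissue = default_run.data.tissue
    ratio = tissue["cns"] / tissue["whole_body"]
    assert int((ratio < 0.05).sum()) == SyntheticConfig().n_nonsynaptic_cnslow


def test_tissue_table_excludes_adult_only_genes(small_data):
    assert not set(small_data.truth.genes("adult_only")) & set(small_data.tissue.index)


@pytest.mark.parametrize("frac,expect_all,expect_none", [(1.0, True, False), (0.0, False, True)])
def test_planted_term_fraction_limits(frac, expect_all, expect_none):
    from synapred import generate_annotations

    cfg = dataclasses.replace(TINY, planted_term_frac=frac)
    _, truth = generate_expression(cfg)
    sets = generate_annotations(cfg, truth)
    planted = sets[PLANTED_TERM]
    synaptic = set(truth.synaptic)
    if expect_all:
        assert synaptic <= planted
    if expect_none:
        assert not planted & synaptic


def test_planted_term_is_enriched_in_true_synaptic_set(small_data):
    truth = small_data.truth
    background = set(truth.table.index[truth.table["label"] != "adult_only"])
    enr = term_enrichment(
        set(truth.synaptic), background, small_data.gene_sets[PLANTED_TERM]
    )
    assert enr > 1.0


def test_homology_limits():
    _, truth = generate_expression(TINY)
    empty, _ = generate_homology(dataclasses.replace(TINY, homolog_frac=0.0), truth)
    assert empty == {}
    full, hs = generate_homology(
        dataclasses.replace(TINY, homolog_frac=1.0, hs_synaptic_rate=1.0), truth
    )
    assert all(full[g] & hs for g in truth.synaptic)


def test_no_elevated_rate_puts_overlap_inside_null(small_data):
    """With the synaptic annotation rate forced to the base rate, the true
    synaptic set's homolog overlap is unexceptional under the resampling null."""
    cfg = dataclasses.replace(
        SMALL := small_data.config, hs_synaptic_rate=SMALL.hs_base_rate
    )
    homology, hs = generate_homology(cfg, small_data.truth)
    truth = small_data.truth
    background = set(truth.table.index[truth.table["label"] != "adult_only"])
    synaptic = set(truth.synaptic)
    observed, _ = synaptic_homolog_overlap(synaptic, homology, hs)
    null = random_list_null(
        background, len(synaptic), homology, hs, reps=400, seed=5
    )
    assert null.percentile(0.5) <= observed <= null.percentile(99.5)
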