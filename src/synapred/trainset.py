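"""Training-set construction from the curated positive list and two negative criteria.

Negatives are genes that can be argued, on biology alone, to be irrelevant
for synapse assembly: (1) genes nearly silent in the larval CNS relative to
the whole body (CNS / whole-body ratio strictly below 0.05) during a stage
of intense synaptogenesis, and (2) genes with extreme sex-biased adult
expression (zero in every adult sample of one sex, above 25 FPKM in the
other), since synapses are essentially identical between sexes.  Neither
criterion reads the 24-sample profiles the classifiers consume, so labels
and features stay independent.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .preprocess import FEMALE_COLUMNS, MALE_COLUMNS, validate_matrix
from .simulate import TISSUES, WHOLE_BODY

logger = logging.getLogger(__name__)


@dataclass
class TrainingSet:
    """Disjoint positive / negative gene-id sets with per-criterion provenance."""

    positives: set[str]
    negatives: set[str]
    negatives_cns: set[str] = field(default_factory=set)
    negatives_sex: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        overlap = self.positives & self.negatives
        if overlap:
            raise ValueError(f"positives and negatives overlap: {sorted(overlap)[:5]}")

    @property
    def genes(self) -> set[str]:
        return self.positives | self.negatives

    def labels(self) -> pd.Series:
        """Gene id -> y label (1 = synaptic, 0 = non-synaptic), sorted by id."""
        ids = sorted(self.positives) + sorted(self.negatives)
        y = [1] * len(self.positives) + [0] * len(self.negatives)
        return pd.Series(y, index=ids, name="label").sort_index()


def negatives_by_cns_ratio(table: pd.DataFrame, ratio_max: float = 0.05) -> set[str]:
    """Genes whose larval CNS expression is below ``ratio_max`` of whole-body mean.

    Only genes with whole-body mean > 0 are evaluated; the comparison is
    strict (a ratio of exactly 0.05 is not selected).
    """
    for col in ("cns", WHOLE_BODY):
        if col not in table.columns:
            raise ValueError(f"tissue table lacks required column {col!r}")
    wb = table[WHOLE_BODY]
    positive_wb = wb > 0
    ratio = table.loc[positive_wb, "cns"] / wb[positive_wb]
    return set(ratio.index[ratio < ratio_max])


def negatives_by_sex_bias(matrix: pd.DataFrame, fpkm_min: float = 25.0) -> set[str]:
    """Genes with zero expression in all adult samples of one sex and
    above ``fpkm_min`` FPKM in at least one adult sample of the other."""
    matrix = validate_matrix(matrix)
    female = matrix.loc[:, list(FEMALE_COLUMNS)]
    male = matrix.loc[:, list(MALE_COLUMNS)]
    female_zero = (female == 0).all(axis=1)
    male_zero = (male == 0).all(axis=1)
    female_high = (female > fpkm_min).any(axis=1)
    male_high = (male > fpkm_min).any(axis=1)
    selected = (female_zero & male_high) | (male_zero & female_high)
    return set(matrix.index[selected])


def build_training_set(
    positives: set[str] | list[str],
    matrix: pd.DataFrame,
    tissue: pd.DataFrame,
    expressed: pd.Index | set[str],
    ratio_max: float = 0.05,
    fpkm_min: float = 25.0,
) -> tuple[TrainingSet, set[str]]:
    """Assemble the labeled training set and the classification set.

    Negatives are the union of the two criteria restricted to expressed
    genes, minus the curated positives (curated evidence outranks the
    heuristics; conflicts are logged).  The classification set is every
    expressed gene not in the training set, so training genes are never
    scored.
    """
    expressed = set(expressed)
    positives = set(positives)
    absent = positives - expressed
    if absent:
        logger.warning(
            "%d positive genes absent from the expressed set and excluded: %s",
            len(absent),
            sorted(absent)[:5],
        )
        positives -= absent

    cns = negatives_by_cns_ratio(tissue, ratio_max=ratio_max) & expressed
    sex = negatives_by_sex_bias(matrix, fpkm_min=fpkm_min) & expressed
    negatives = (cns | sex) - positives
    conflict = (cns | sex) & positives
    if conflict:
        logger.info(
            "%d curated positives also met a negative criterion and stay positive: %s",
            len(conflict),
            sorted(conflict)[:5],
        )

    training = TrainingSet(
        positives=positives,
        negatives=negatives,
        negatives_cns=cns - positives,
        negatives_sex=sex - positives,
    )
    classification = expressed - training.genes
    assert not (training.genes & classification)
    assert len(training.genes) + len(classification) == len(expressed)
    return training, classification
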