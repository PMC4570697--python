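"""Tissue-specificity and human-homolog evaluations of a catalogue.

Two orthogonal lines of support for a putative synaptic-gene catalogue:

* GTSDE (genes with tissue-specific differential expression): a gene is
  assigned to a tissue when it is at least moderately expressed there
  (>= high_min) and very low (<= low_max) in all four other tissues at the
  third larval instar.  A genuine synaptic catalogue should be dominated by
  CNS-specific genes and depleted of genes specific to non-innervated
  tissues.
* Human-homolog overlap: the count of catalogue genes whose human homolog
  already carries a synapse annotation, compared against a resampling null
  built from random gene lists of the same size.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import TISSUES


class ConfigurationError(ValueError):
    pass


def gtsde(
    table: pd.DataFrame, high_min: float = 4.0, low_max: float = 1.0
) -> dict[str, set[str]]:
    """Per-tissue lists of tissue-specifically expressed genes.

    A gene lands in tissue T's list iff expression(T) >= high_min and
    expression(T') <= low_max for every other tissue; the lists are pairwise
    disjoint by construction (high_min > low_max).  Genes qualifying nowhere
    are unassigned.
    """
    if not high_min > low_max >= 0:
        raise ConfigurationError("high_min > low_max >= 0 required")
    missing = [t for t in TISSUES if t not in table.columns]
    if missing:
        raise ValueError(f"tissue table lacks columns: {missing}")
    lists: dict[str, set[str]] = {}
    values = table.loc[:, list(TISSUES)]
    for tissue in TISSUES:
        others = [t for t in TISSUES if t != tissue]
        mask = (values[tissue] >= high_min) & (values[others] <= low_max).all(axis=1)
        lists[tissue] = set(values.index[mask])
    return lists


def gtsde_proportions(
    catalogue: set[str], lists: dict[str, set[str]]
) -> pd.Series:
    """Percentage of the catalogue's tissue-specific genes per tissue.

    Denominator is the catalogue's intersection with the union of all five
    lists; a catalogue with no tissue-specific member yields all-NaN
    ("missing").
    """
    catalogue = set(catalogue)
    union = set().union(*lists.values()) if lists else set()
    denom = len(catalogue & union)
    if denom == 0:
        return pd.Series({t: float("nan") for t in TISSUES}, name="percent")
    return pd.Series(
        {t: 100.0 * len(catalogue & lists.get(t, set())) / denom for t in TISSUES},
        name="percent",
    )


def synaptic_homolog_overlap(
    catalogue: set[str],
    homology: dict[str, set[str]],
    human_synaptic: set[str],
    probs: pd.DataFrame | None = None,
) -> tuple[int, pd.DataFrame]:
    """Catalogue genes with at least one human homolog annotated as synaptic.

    Counting is gene-level: a fly gene with several synaptic homologs counts
    once.  The returned table lists each such gene with the mean of its three
    model probabilities (when a probability table is supplied) and its
    synaptic homolog ids.
    """
    rows = []
    for gene in sorted(set(catalogue)):
        hits = sorted(homology.get(gene, set()) & human_synaptic)
        if not hits:
            continue
        mean_p = float("nan")
        if probs is not None and gene in probs.index and "mean_p" in probs.columns:
            mean_p = float(probs.loc[gene, "mean_p"])
        rows.append((gene, mean_p, ";".join(hits)))
    table = pd.DataFrame(rows, columns=["gene_id", "mean_p", "human_homologs"])
    if len(table):
        table = table.sort_values(
            ["mean_p", "gene_id"], ascending=[False, True], kind="stable"
        ).reset_index(drop=True)
    return len(table), table


@dataclass
class NullDistribution:
    """Resampled null of synaptic-homolog counts for random gene lists."""

    counts: np.ndarray
    size: int
    reps: int
    seed: int

    @property
    def mean(self) -> float:
        return float(np.mean(self.counts))

    @property
    def interval95(self) -> tuple[float, float]:
        return (
            float(np.percentile(self.counts, 2.5)),
            float(np.percentile(self.counts, 97.5)),
        )

    def percentile(self, q: float) -> float:
        return float(np.percentile(self.counts, q))


def random_list_null(
    background: set[str],
    size: int,
    homology: dict[str, set[str]],
    human_synaptic: set[str],
    gene_sets: dict[str, set[str]] | None = None,
    synapse_terms: set[str] | None = None,
    reps: int = 100,
    seed: int = 0,
) -> NullDistribution:
    """Null distribution of the synaptic-homolog count for random gene lists.

    Each repetition draws ``size`` genes uniformly without replacement from
    the background, removes those annotated to any synapse-related term
    (mirroring the annotation exclusion applied to the real catalogue, after
    the draw so the draw size matches the catalogue's pre-exclusion size),
    and counts genes with a synaptic human homolog.
    """
    background_list = sorted(set(background))
    if size > len(background_list):
        raise ValueError(
            f"draw size {size} exceeds background of {len(background_list)} genes"
        )
    if reps < 1:
        raise ValueError("reps must be >= 1")
    annotated: set[str] = set()
    if gene_sets and synapse_terms:
        for term in synapse_terms:
            annotated |= gene_sets.get(term, set())
    has_synaptic_homolog = {
        g for g, homs in homology.items() if homs & human_synaptic
    }
    rng = np.random.default_rng(int(seed))
    arr = np.asarray(background_list, dtype=object)
    counts = np.empty(reps, dtype=int)
    for r in range(reps):
        draw = set(rng.choice(arr, size=size, replace=False))
        counts[r] = len((draw - annotated) & has_synaptic_homolog)
    return NullDistribution(counts=counts, size=size, reps=reps, seed=int(seed))
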