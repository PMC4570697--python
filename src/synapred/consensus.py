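"""Threshold sweep, per-model catalogues, consensus intersection, final catalogue.

A catalogue at threshold t is the set of classified genes whose estimated
probability strictly exceeds t ("must exceed"); the consensus catalogue is
the intersection of the three per-model catalogues.  Raising the threshold
from 0.5 to 0.9 yields a nested, shrinking series of catalogues; the final
catalogue removes from the top-threshold consensus any gene already carrying
a synapse-related annotation, leaving only novel candidates.
"""
from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .classifiers import MODEL_COLUMNS, MODELS

DEFAULT_THRESHOLDS: tuple[float, ...] = (0.5, 0.6, 0.7, 0.8, 0.9)


@dataclass
class Catalogue:
    """A gene-id set with its provenance (model and threshold)."""

    genes: set[str]
    model: str
    threshold: float

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes


def threshold_catalogue(probs: pd.DataFrame, model: str, t: float) -> Catalogue:
    """Genes whose probability under ``model`` strictly exceeds ``t``."""
    if model not in MODEL_COLUMNS:
        raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")
    if not 0.0 <= t <= 1.0:
        raise ValueError(f"threshold {t} outside [0, 1]")
    col = MODEL_COLUMNS[model]
    return Catalogue(set(probs.index[probs[col] > t]), model, t)


def consensus_catalogue(probs: pd.DataFrame, t: float) -> Catalogue:
    """Genes called synaptic by all three models at threshold ``t``."""
    genes = set(probs.index)
    for model in MODELS:
        genes &= threshold_catalogue(probs, model, t).genes
    return Catalogue(genes, "consensus", t)


def coincidence(
    probs: pd.DataFrame, reference: str, other: str, t: float = 0.5
) -> float:
    """Percentage of ``reference``-positive genes also positive under ``other``.

    Returns NaN when the reference catalogue is empty.
    """
    ref = threshold_catalogue(probs, reference, t).genes
    if not ref:
        return float("nan")
    oth = threshold_catalogue(probs, other, t).genes
    return 100.0 * len(ref & oth) / len(ref)


def sweep(
    probs: pd.DataFrame, thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
) -> pd.DataFrame:
    """Catalogue and Venn-intersection sizes per model across thresholds.

    Rows: the three models, their pairwise intersections, and the three-way
    consensus.  Every row is non-increasing left to right, since raising the
    threshold can only shrink a catalogue.
    """
    thresholds = tuple(thresholds)
    if list(thresholds) != sorted(thresholds):
        raise ValueError("thresholds must be sorted ascending")
    rows: dict[str, list[int]] = {}
    for t in thresholds:
        cats = {m: threshold_catalogue(probs, m, t).genes for m in MODELS}
        sizes = {
            "knn": len(cats["knn"]),
            "rf": len(cats["rf"]),
            "svm": len(cats["svm"]),
            "knn_rf": len(cats["knn"] & cats["rf"]),
            "knn_svm": len(cats["knn"] & cats["svm"]),
            "rf_svm": len(cats["rf"] & cats["svm"]),
            "consensus": len(cats["knn"] & cats["rf"] & cats["svm"]),
        }
        for name, size in sizes.items():
            rows.setdefault(name, []).append(size)
    table = pd.DataFrame(rows, index=list(thresholds)).T
    table.index.name = "catalogue"
    table.columns.name = "threshold"
    # monotonicity is structural; assert it on every run
    assert (table.diff(axis=1).fillna(0) <= 0).all().all()
    return table


def final_catalogue(
    consensus: Catalogue,
    gene_sets: dict[str, set[str]],
    synapse_terms: set[str],
) -> tuple[Catalogue, set[str]]:
    """Remove genes already annotated to any synapse-related term.

    Returns the final catalogue of novel candidates plus the excluded,
    already-annotated genes.  An empty ``synapse_terms`` set performs no
    exclusion (with a warning), since there is nothing to exclude by.
    """
    if not synapse_terms:
        import warnings

        warnings.warn("empty synapse-term set: no annotation exclusion performed")
        return Catalogue(set(consensus.genes), "final", consensus.threshold), set()
    annotated: set[str] = set()
    for term in synapse_terms:
        annotated |= gene_sets.get(term, set())
    excluded = consensus.genes & annotated
    final = Catalogue(consensus.genes - excluded, "final", consensus.threshold)
    assert len(final.genes) + len(excluded) == len(consensus.genes)
    return final, excluded
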