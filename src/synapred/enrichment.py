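"""Gene-set enrichment of a catalogue against a custom background.

For a term with B genes in a background of N, of which b fall inside a
catalogue of n genes, enrichment is the ratio of term frequencies
(b/n) / (B/N); significance is the hypergeometric upper-tail probability
P[X >= b] with X ~ Hypergeometric(N, B, n), corrected across all tested
terms by the Benjamini-Hochberg step-up procedure.  The background is the
classified gene universe (the expressed genes minus the training set), so
training genes can never drive an enrichment.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .consensus import DEFAULT_THRESHOLDS, consensus_catalogue

ENRICHMENT_COLUMNS = ("term", "N", "B", "n", "b", "enrichment", "p", "q")


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg q-values, in the input order.

    q_(i) = min_{j >= i} (m * p_(j) / j) over the sorted p-values, capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def enrich(
    catalogue: set[str],
    background: set[str],
    gene_sets: dict[str, set[str]],
    p_max: float = 1e-4,
    q_max: float = 1e-3,
    significant_only: bool = True,
) -> pd.DataFrame:
    """Enrichment of ``catalogue`` in every term, within ``background``.

    Term membership (b, B) is recomputed inside the background before any
    arithmetic.  Returns one row per term with (N, B, n, b, enrichment, p, q),
    sorted by p; when ``significant_only`` the table is filtered to
    p < p_max and q < q_max.  BH correction always runs over all tested
    terms (one family per catalogue).
    """
    catalogue = set(catalogue)
    background = set(background)
    stray = catalogue - background
    if stray:
        raise ValueError(
            f"{len(stray)} catalogue genes outside the background: {sorted(stray)[:5]}"
        )
    N = len(background)
    n = len(catalogue)
    records = []
    for term, members in gene_sets.items():
        in_bg = members & background
        B = len(in_bg)
        b = len(in_bg & catalogue)
        if n == 0 or B == 0:
            enr = float("nan") if (n == 0 or B == 0) else 0.0
        else:
            enr = (b / n) / (B / N)
        p = float(hypergeom.sf(b - 1, N, B, n)) if N else float("nan")
        records.append((term, N, B, n, b, enr, p))
    table = pd.DataFrame(records, columns=ENRICHMENT_COLUMNS[:-1])
    table["q"] = bh_fdr(table["p"].to_numpy()) if len(table) else []
    table = table.sort_values("p", kind="stable").reset_index(drop=True)
    if significant_only:
        table = table[(table["p"] < p_max) & (table["q"] < q_max)].reset_index(
            drop=True
        )
    return table


def term_enrichment(
    catalogue: set[str], background: set[str], term_genes: set[str]
) -> float:
    """The (b/n)/(B/N) ratio for a single term; NaN for an empty catalogue."""
    catalogue = set(catalogue) & set(background)
    N, n = len(background), len(catalogue)
    in_bg = set(term_genes) & set(background)
    B = len(in_bg)
    if n == 0 or B == 0 or N == 0:
        return float("nan")
    return (len(in_bg & catalogue) / n) / (B / N)


def enrichment_by_threshold(
    probs: pd.DataFrame,
    thresholds: tuple[float, ...],
    background: set[str],
    gene_sets: dict[str, set[str]],
    term: str,
) -> pd.Series:
    """Enrichment of one term in the consensus catalogue at each threshold.

    Empty catalogues yield NaN ("missing") for that threshold.
    """
    if term not in gene_sets:
        raise KeyError(f"term {term!r} not found in the gene-set collection")
    values = {
        t: term_enrichment(
            consensus_catalogue(probs, t).genes, background, gene_sets[term]
        )
        for t in thresholds
    }
    series = pd.Series(values, name=f"enrichment[{term}]")
    series.index.name = "threshold"
    return series
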