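"""Filtering and normalization of the developmental expression matrix.

The input is a genes x 30 FPKM table covering the fly life cycle: 24
whole-body samples spanning embryo (E1..E12), larva (L1..L6) and pupa
(P1..P6), plus 6 adult samples (three timepoints, sequenced separately
per sex).  Classification features are the 24 stage samples only; each
gene's stage series is divided by its own maximum so that profile shape,
not absolute transcript abundance, drives the classifiers.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

STAGE_COLUMNS: tuple[str, ...] = tuple(
    [f"E{i}" for i in range(1, 13)]
    + [f"L{i}" for i in range(1, 7)]
    + [f"P{i}" for i in range(1, 7)]
)
ADULT_COLUMNS: tuple[str, ...] = ("A1f", "A1m", "A2f", "A2m", "A3f", "A3m")
FEMALE_COLUMNS: tuple[str, ...] = ("A1f", "A2f", "A3f")
MALE_COLUMNS: tuple[str, ...] = ("A1m", "A2m", "A3m")
ALL_COLUMNS: tuple[str, ...] = STAGE_COLUMNS + ADULT_COLUMNS

# The two waves of synaptogenesis: late embryo (stage samples 7-12) and
# pupa (samples 19-24), separated by the larval synapse-disassembly trough.
EMBRYO_WAVE: tuple[str, ...] = STAGE_COLUMNS[6:12]
LARVAL_TROUGH: tuple[str, ...] = STAGE_COLUMNS[12:18]
PUPAL_WAVE: tuple[str, ...] = STAGE_COLUMNS[18:24]


class SchemaError(ValueError):
    """Raised when an expression table does not match the 30-column layout."""


def validate_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Check the 30-column schema and return the matrix in canonical column order.

    Raises
    ------
    SchemaError
        If any expected column is missing, gene ids are duplicated, or any
        FPKM value is negative or missing.
    """
    missing = [c for c in ALL_COLUMNS if c not in matrix.columns]
    if missing:
        raise SchemaError(f"expression matrix lacks required columns: {missing}")
    out = matrix.loc[:, list(ALL_COLUMNS)]
    if out.index.duplicated().any():
        dups = out.index[out.index.duplicated()].unique().tolist()[:5]
        raise SchemaError(f"duplicated gene ids: {dups}")
    values = out.to_numpy(dtype=float)
    if np.isnan(values).any():
        bad = out.index[np.isnan(values).any(axis=1)].tolist()[:5]
        raise SchemaError(f"missing FPKM values for genes: {bad}")
    if (values < 0).any():
        bad = out.index[(values < 0).any(axis=1)].tolist()[:5]
        raise SchemaError(f"negative FPKM values for genes: {bad}")
    return out


def filter_expressed(matrix: pd.DataFrame) -> pd.Index:
    """Genes with transcript level above zero in at least one of the 24 stage samples.

    The complement within the matrix consists of adult-only genes (expressed
    exclusively in the six adult samples) and genes with no expression at all;
    both are dropped because the temporal signature of interest lives in the
    embryonic and pupal samples.
    """
    matrix = validate_matrix(matrix)
    stage = matrix.loc[:, list(STAGE_COLUMNS)]
    return matrix.index[(stage > 0).any(axis=1)]


def normalize(matrix: pd.DataFrame, genes: pd.Index | None = None) -> pd.DataFrame:
    """Divide each gene's 24-sample stage series by its maximum.

    Returns the genes x 24 feature table with every profile in [0, 1] and a
    maximum of exactly 1.  The six adult columns are not part of the feature
    vector (they are consumed only by the sex-bias training criterion, on raw
    FPKM).

    Raises
    ------
    ValueError
        If any requested gene has a stage maximum of zero; such genes must be
        removed by :func:`filter_expressed` first.
    """
    matrix = validate_matrix(matrix)
    stage = matrix.loc[:, list(STAGE_COLUMNS)]
    if genes is not None:
        missing = [g for g in genes if g not in stage.index]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing[:5]}")
        stage = stage.loc[list(genes)]
    maxima = stage.max(axis=1)
    zero = maxima[maxima <= 0]
    if len(zero):
        raise ValueError(
            f"cannot normalize genes with all-zero stage profile: {zero.index.tolist()[:5]}"
        )
    return stage.div(maxima, axis=0)
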