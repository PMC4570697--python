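"""Readers and writers for the pipeline's exchange formats.

TSV with a header row is the exchange format throughout (expression matrix,
tissue table, probability table, sweep table); gene sets travel as GMT and
gene lists as one-id-per-line text.  Writers prepend ``#``-prefixed comment
lines carrying run metadata (seed, config hash); readers skip them.
"""
from __future__ import annotations

import io as _io
from pathlib import Path

import pandas as pd

from .preprocess import ALL_COLUMNS, SchemaError, validate_matrix
from .simulate import TISSUE_COLUMNS


def _metadata_lines(metadata: dict | None) -> str:
    if not metadata:
        return ""
    return "".join(f"# {k}={v}\n" for k, v in metadata.items())


def write_tsv(df: pd.DataFrame, path: str | Path, metadata: dict | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_metadata_lines(metadata))
        df.to_csv(fh, sep="\t")


def read_tsv(path: str | Path, index_col: int | str = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


def write_expression(
    matrix: pd.DataFrame, path: str | Path, metadata: dict | None = None
) -> None:
    write_tsv(validate_matrix(matrix), path, metadata)


def read_expression(path: str | Path) -> pd.DataFrame:
    raw = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    if list(raw.columns) != list(ALL_COLUMNS):
        missing = [c for c in ALL_COLUMNS if c not in raw.columns]
        if missing:
            raise SchemaError(f"{path}: missing columns {missing}")
    bad = raw.index[raw.isna().any(axis=1)]
    if len(bad):
        # +2: one header line plus 1-based numbering (comment lines aside)
        lines = [int(raw.index.get_loc(g)) + 2 for g in bad[:5]]
        raise SchemaError(
            f"{path}: malformed rows (wrong column count) near lines {lines}"
        )
    return validate_matrix(raw)


def write_tissue_table(
    table: pd.DataFrame, path: str | Path, metadata: dict | None = None
) -> None:
    write_tsv(table.loc[:, list(TISSUE_COLUMNS)], path, metadata)


def read_tissue_table(path: str | Path) -> pd.DataFrame:
    table = read_tsv(path)
    missing = [c for c in TISSUE_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"{path}: tissue table missing columns {missing}")
    return table.loc[:, list(TISSUE_COLUMNS)]


def write_gene_list(
    genes, path: str | Path, metadata: dict | None = None
) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_metadata_lines(metadata))
        for gene in sorted(set(genes)):
            fh.write(f"{gene}\n")


def read_gene_list(path: str | Path) -> list[str]:
    genes = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            genes.append(line)
    return genes


def write_gmt(
    gene_sets: dict[str, set[str]],
    path: str | Path,
    descriptions: dict[str, str] | None = None,
) -> None:
    """Write term -> gene-set map in GMT format (term, description, genes...)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for term in sorted(gene_sets):
            genes = "\t".join(sorted(gene_sets[term]))
            desc = descriptions.get(term, term)
            fh.write(f"{term}\t{desc}\t{genes}\n" if genes else f"{term}\t{desc}\n")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    gene_sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise SchemaError(
                    f"{path}:{lineno}: GMT line needs at least term and description"
                )
            term = fields[0]
            if term in gene_sets:
                raise SchemaError(f"{path}:{lineno}: duplicate term {term!r}")
            gene_sets[term] = {g for g in fields[2:] if g}
    return gene_sets


def write_homology(
    homology: dict[str, set[str]], path: str | Path, metadata: dict | None = None
) -> None:
    """Two-column TSV: fly gene id, human homolog id (one pair per line)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_metadata_lines(metadata))
        fh.write("gene_id\thuman_id\n")
        for gene in sorted(homology):
            for human in sorted(homology[gene]):
                fh.write(f"{gene}\t{human}\n")


def read_homology(path: str | Path) -> dict[str, set[str]]:
    homology: dict[str, set[str]] = {}
    with open(path) as fh:
        header_seen = False
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise SchemaError(f"{path}:{lineno}: expected 2 columns")
            if not header_seen:
                header_seen = True
                if fields[0] == "gene_id":
                    continue
            homology.setdefault(fields[0], set()).add(fields[1])
    return homology


def write_probabilities(
    probs: pd.DataFrame, path: str | Path, metadata: dict | None = None
) -> None:
    write_tsv(probs, path, metadata)


def read_probabilities(path: str | Path) -> pd.DataFrame:
    probs = read_tsv(path)
    missing = [c for c in ("p_knn", "p_rf", "p_svm") if c not in probs.columns]
    if missing:
        raise SchemaError(f"{path}: probability table missing columns {missing}")
    return probs


def frame_to_string(df: pd.DataFrame) -> str:
    buf = _io.StringIO()
    df.to_csv(buf, sep="\t")
    return buf.getvalue()
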