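"""TSV readers and writers (the package's sole exchange dialect).

Expression and genotype matrices: first column is the row identifier, header
row carries sample IDs, tab-separated, UTF-8.  Pairs files: two columns
(eQTL ID, gene ID) with a header.  IDs must match ``[A-Za-z0-9._:-]+``.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ParseError
from .preprocess import ExpressionMatrix, GenotypeMatrix
from .scores import ScoreSet

__all__ = [
    "read_expression",
    "read_genotypes",
    "read_pairs",
    "read_edges",
    "write_expression",
    "write_genotypes",
    "write_pairs",
    "write_edges",
    "write_score_matrix",
    "write_scores_long",
]

_ID_RE = re.compile(r"^[A-Za-z0-9._:-]+$")
_PROB_FMT = "%.6f"


def _check_ids(ids: list[str], path: str, what: str) -> None:
    for i, ident in enumerate(ids):
        if not _ID_RE.match(str(ident)):
            raise ParseError(f"invalid {what} ID {ident!r}", path=path, line=i + 1)


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ParseError("file not found", path=str(path))
    try:
        df = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"unreadable TSV: {exc}", path=str(path)) from exc
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ParseError(f"duplicate row ID {dup!r}", path=str(path))
    return df


def _numeric(df: pd.DataFrame, path: str, integer: bool) -> np.ndarray:
    try:
        values = df.to_numpy(dtype=float)
    except ValueError:
        for i, (_, row) in enumerate(df.iterrows()):
            for cell in row:
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise ParseError(f"non-numeric cell {cell!r}", path=path,
                                     line=i + 2) from None
        raise
    if np.any(~np.isfinite(values)):
        bad = int(np.argwhere(~np.isfinite(values))[0, 0])
        raise ParseError("missing or non-finite cell", path=path, line=bad + 2)
    if integer and np.any(values != np.round(values)):
        bad = int(np.argwhere(values != np.round(values))[0, 0])
        raise ParseError("genotype cells must be integers", path=path, line=bad + 2)
    return values


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a genes x samples expression TSV."""
    df = _read_table(path)
    _check_ids(list(df.index), str(path), "gene")
    _check_ids(list(df.columns), str(path), "sample")
    values = _numeric(df, str(path), integer=False)
    return ExpressionMatrix(list(df.index), values, list(df.columns))


def read_genotypes(path: str | Path) -> GenotypeMatrix:
    """Read a variants x samples integer genotype TSV."""
    df = _read_table(path)
    _check_ids(list(df.index), str(path), "variant")
    _check_ids(list(df.columns), str(path), "sample")
    values = _numeric(df, str(path), integer=True).astype(np.int64)
    return GenotypeMatrix(list(df.index), values, list(df.columns))


def read_pairs(path: str | Path) -> list[tuple[str, str]]:
    """Read the 2-column (eQTL, gene) pairing TSV."""
    path = Path(path)
    if not path.exists():
        raise ParseError("file not found", path=str(path))
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if df.shape[1] != 2:
        raise ParseError(f"expected 2 columns, found {df.shape[1]}", path=str(path))
    pairs = [(str(e), str(a)) for e, a in df.itertuples(index=False)]
    _check_ids([e for e, _ in pairs], str(path), "eQTL")
    _check_ids([a for _, a in pairs], str(path), "gene")
    return pairs


def read_edges(path: str | Path) -> set[tuple[str, str]]:
    """Read a 2-column (regulator, target) groundtruth TSV."""
    return set(read_pairs(path))


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    pd.DataFrame(matrix.values, index=matrix.gene_ids,
                 columns=matrix.sample_ids).to_csv(path, sep="\t",
                                                   index_label="gene")


def write_genotypes(matrix: GenotypeMatrix, path: str | Path) -> None:
    pd.DataFrame(matrix.values, index=matrix.variant_ids,
                 columns=matrix.sample_ids).to_csv(path, sep="\t",
                                                   index_label="variant")


def write_pairs(pairs: list[tuple[str, str]], path: str | Path) -> None:
    pd.DataFrame(pairs, columns=["eqtl", "gene"]).to_csv(path, sep="\t", index=False)


def write_edges(edges: set[tuple[str, str]], path: str | Path) -> None:
    pd.DataFrame(sorted(edges), columns=["regulator", "target"]).to_csv(
        path, sep="\t", index=False)


def write_score_matrix(scoreset: ScoreSet, score_name: str, path: str | Path) -> None:
    """One score as a matrix TSV: rows = A genes, columns = B genes,
    probabilities with 6 decimals (NaN for the excluded self-pairs)."""
    df = pd.DataFrame(scoreset.by_name(score_name),
                      index=scoreset.pair_gene_ids,
                      columns=scoreset.target_gene_ids)
    df.to_csv(path, sep="\t", index_label="gene", float_format=_PROB_FMT)


def write_scores_long(scoreset: ScoreSet, path: str | Path) -> None:
    """Long-format TSV: E, A, B and all per-test and composite scores."""
    names = ["P0", "P2", "P3", "P4", "P5", "PT", "Pnew"]
    mats = [scoreset.by_name(n) for n in names]
    rows = []
    for i, (e, a) in enumerate(zip(scoreset.pair_eqtl_ids, scoreset.pair_gene_ids)):
        for j, b in enumerate(scoreset.target_gene_ids):
            if a == b or not np.isfinite(mats[0][i, j]):
                continue
            rows.append([e, a, b] + [m[i, j] for m in mats])
    pd.DataFrame(rows, columns=["E", "A", "B"] + names).to_csv(
        path, sep="\t", index=False, float_format=_PROB_FMT)
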