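"""Readers and writers for the framework's tabular formats.

Expression matrices and sample tables are tab-delimited UTF-8 text with '.'
decimals; probeset best-match tables are CSV in the Affymetrix
comparison-spreadsheet style; gene lists are one-ID-per-line text with '#'
comments; result reports are JSON.
"""

from __future__ import annotations

import warnings
from os import PathLike
from pathlib import Path
from typing import Sequence

import pandas as pd

from .datatypes import ExpressionMatrix, SampleInfo, ProbesetMap, normalize_sex
from .exceptions import FormatError, ValidationError

PathT = str | PathLike


def read_expression_matrix(path: PathT) -> ExpressionMatrix:
    """Read a genes x samples log2 expression matrix from TSV.

    First row holds sample IDs (the corner cell is ignored), first column
    gene IDs, the body decimal numbers.  Row and column order is preserved.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot parse expression matrix {path}: {exc}") from exc
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique()[0]
        raise FormatError(f"duplicate gene ID {dup!r} in {path}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()].unique()[0]
        raise FormatError(f"duplicate sample ID {dup!r} in {path}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        r, c = next(zip(*bad.to_numpy().nonzero()))
        raise FormatError(
            f"non-numeric cell {df.iat[r, c]!r} at gene {df.index[r]!r}, "
            f"sample {df.columns[c]!r} in {path}"
        )
    if numeric.isna().to_numpy().any():
        raise FormatError(f"missing value in expression matrix {path}")
    try:
        return ExpressionMatrix(numeric)
    except ValidationError as exc:
        raise FormatError(str(exc)) from exc


def write_expression_matrix(matrix: ExpressionMatrix, path: PathT) -> None:
    """Write a matrix as TSV with full float precision (round-trips exactly)."""
    matrix.data.to_csv(path, sep="\t", index_label="gene_id", float_format="%.17g")


_SAMPLE_COLUMNS = ("sample_id", "age", "sex", "group")


def read_sample_table(path: PathT) -> list[SampleInfo]:
    """Read a TSV sample table with header columns sample_id, age, sex, group."""
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:  # pragma: no cover
        raise FormatError(f"cannot parse sample table {path}: {exc}") from exc
    missing = [c for c in _SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(
            f"sample table {path} lacks columns {missing}; found {list(df.columns)}"
        )
    samples = []
    for _, row in df.iterrows():
        try:
            age = float(row["age"])
        except (TypeError, ValueError):
            raise ValidationError(
                f"sample {row['sample_id']!r}: unparseable age {row['age']!r}"
            ) from None
        samples.append(
            SampleInfo(
                sample_id=str(row["sample_id"]),
                age=age,
                sex=normalize_sex(row["sex"]),
                group=str(row["group"]),
            )
        )
    return samples


def write_sample_table(samples: Sequence[SampleInfo], path: PathT) -> None:
    pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "age": [repr(float(s.age)) for s in samples],
            "sex": [s.sex for s in samples],
            "group": [s.group for s in samples],
        }
    ).to_csv(path, sep="\t", index=False)


def read_best_match_table(path: PathT, col_a: str, col_b: str) -> ProbesetMap:
    """Read a probeset best-match CSV, keeping (col_a, col_b) pairs.

    Rows with either field empty are dropped; duplicate pairs collapse to one.
    """
    try:
        df = pd.read_csv(path, dtype=str)
    except Exception as exc:  # pragma: no cover
        raise FormatError(f"cannot parse best-match table {path}: {exc}") from exc
    for col in (col_a, col_b):
        if col not in df.columns:
            raise FormatError(
                f"column {col!r} absent from {path}; available: {list(df.columns)}"
            )
    pairs = set()
    for a, b in zip(df[col_a], df[col_b]):
        a = "" if pd.isna(a) else str(a).strip()
        b = "" if pd.isna(b) else str(b).strip()
        if a and b:
            pairs.add((a, b))
    return ProbesetMap(frozenset(pairs))


def read_gene_list(path: PathT) -> set[str]:
    """Read a one-ID-per-line gene list; '#' comments and blank lines ignored."""
    ids: set[str] = set()
    for line in Path(path).read_text().splitlines():
        token = line.strip()
        if token and not token.startswith("#"):
            ids.add(token)
    if not ids:
        warnings.warn(f"gene list {path} is empty", UserWarning, stacklevel=2)
    return ids


def write_gene_list(ids: set[str], path: PathT) -> None:
    Path(path).write_text("\n".join(sorted(ids)) + "\n")
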