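"""Readers and writers for the tabular formats the pipeline touches.

All readers validate strictly and reject malformed cells with the file
coordinates (gene/sample id or line number) rather than coercing them.
Gene identifiers are opaque, case-sensitive strings: the cohorts this
pipeline targets mix HGNC symbols, mitochondrial genes and lncRNA names,
and no identifier mapping is attempted.
"""
from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import CountsMatrix, GeneSet, GeneSetCollection, SampleMetadata
from .errors import FormatError

logger = logging.getLogger(__name__)

_SEPARATORS = {"tsv": "\t", "csv": ","}

#: accepted spellings of a missing clinical value
NA_VALUES = ["", "NA", "na", "n.a.", "NaN", "nan"]

#: interaction evidence channels understood by the edge-list reader
CHANNELS = ("physical", "textmining", "database", "combined")

EDGE_COLUMNS = ("protein_a", "protein_b", "channel", "score")


def _sep(dialect: str) -> str:
    try:
        return _SEPARATORS[dialect]
    except KeyError:
        raise FormatError(f"unknown dialect {dialect!r}; expected 'tsv' or 'csv'") from None


def read_counts(path: str | Path, dialect: str = "tsv") -> CountsMatrix:
    """Read a gene x sample count table (first column = gene ids)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(dialect), index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate gene id {dup!r}")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()][0]
        raise FormatError(f"{path}: duplicate sample id {dup!r}")
    # locate non-numeric / negative / fractional cells with coordinates
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"{path}: non-numeric count {df.iat[i, j]!r} at gene "
            f"{df.index[i]!r}, sample {df.columns[j]!r}"
        )
    if numeric.isna().to_numpy().any():
        i, j = np.argwhere(numeric.isna().to_numpy())[0]
        raise FormatError(
            f"{path}: missing count at gene {df.index[i]!r}, sample {df.columns[j]!r}"
        )
    values = numeric.to_numpy()
    if values.size:
        if (values < 0).any():
            i, j = np.argwhere(values < 0)[0]
            raise FormatError(
                f"{path}: negative count {values[i, j]} at gene "
                f"{df.index[i]!r}, sample {df.columns[j]!r}"
            )
        if (values != np.floor(values)).any():
            i, j = np.argwhere(values != np.floor(values))[0]
            raise FormatError(
                f"{path}: non-integer count {values[i, j]} at gene "
                f"{df.index[i]!r}, sample {df.columns[j]!r}"
            )
    return CountsMatrix(numeric.astype(np.int64))


def write_counts(matrix: CountsMatrix, path: str | Path, dialect: str = "tsv") -> None:
    matrix.frame.to_csv(Path(path), sep=_sep(dialect), index_label="gene")


def read_metadata(path: str | Path, dialect: str = "tsv") -> SampleMetadata:
    """Read a sample metadata table (first column = sample ids).

    Clinical columns are parsed as numeric where possible; empty cells and
    "NA"/"n.a." spellings become missing values.
    """
    path = Path(path)
    df = pd.read_csv(
        path, sep=_sep(dialect), index_col=0, na_values=NA_VALUES, keep_default_na=False
    )
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate sample id {dup!r}")
    for col in df.columns:
        if col in ("group", "batch"):
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        # keep the column textual when it is genuinely non-numeric (e.g. sex)
        if coerced.notna().sum() >= df[col].notna().sum():
            df[col] = coerced
    return SampleMetadata(df)


def write_metadata(metadata: SampleMetadata, path: str | Path, dialect: str = "tsv") -> None:
    metadata.frame.to_csv(Path(path), sep=_sep(dialect), index_label="sample")


def read_expression(path: str | Path, dialect: str = "tsv"):
    from .containers import ExpressionMatrix

    df = pd.read_csv(Path(path), sep=_sep(dialect), index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(df)


def write_expression(expr, path: str | Path, dialect: str = "tsv") -> None:
    expr.frame.to_csv(Path(path), sep=_sep(dialect), index_label="gene")


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: ``name TAB description TAB member...`` per line."""
    path = Path(path)
    sets: dict[str, GeneSet] = {}
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line has {len(parts)} field(s); "
                    "expected name, description and at least one member"
                )
            name, description = parts[0], parts[1]
            members: list[str] = []
            seen: set[str] = set()
            for m in parts[2:]:
                if m and m not in seen:
                    members.append(m)
                    seen.add(m)
            if not members:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} has no members")
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            sets[name] = GeneSet(name, description, tuple(members))
    return GeneSetCollection(sets)


def read_edge_list(path: str | Path) -> pd.DataFrame:
    """Read a STRING-export-style TSV of scored protein-protein edges.

    Columns: protein_a, protein_b, channel, score (decimal in [0, 1]).
    Duplicate undirected edges are kept but logged.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"protein_a": str, "protein_b": str})
    missing = [c for c in EDGE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}; expected {list(EDGE_COLUMNS)}")
    df = df[list(EDGE_COLUMNS)]
    for row, channel in enumerate(df["channel"], start=2):
        if channel not in CHANNELS:
            raise FormatError(f"{path}: line {row}: unknown channel {channel!r}")
    scores = pd.to_numeric(df["score"], errors="coerce")
    if scores.isna().any():
        row = int(np.argwhere(scores.isna().to_numpy())[0][0])
        raise FormatError(f"{path}: line {row + 2}: score {df['score'].iloc[row]!r} is not a number")
    out_of_range = (scores < 0) | (scores > 1)
    if out_of_range.any():
        row = int(np.argwhere(out_of_range.to_numpy())[0][0])
        raise FormatError(
            f"{path}: line {row + 2}: score {scores.iloc[row]} outside [0, 1]"
        )
    df["score"] = scores.astype(float)
    loops = df["protein_a"] == df["protein_b"]
    if loops.any():
        row = int(np.argwhere(loops.to_numpy())[0][0])
        raise FormatError(
            f"{path}: line {row + 2}: self-loop on {df['protein_a'].iloc[row]!r}"
        )
    key = df.apply(
        lambda r: (min(r["protein_a"], r["protein_b"]), max(r["protein_a"], r["protein_b"]), r["channel"]),
        axis=1,
    )
    n_dup = int(key.duplicated().sum())
    if n_dup:
        logger.warning("%s: %d duplicate undirected edge(s) kept", path, n_dup)
    return df.reset_index(drop=True)


def write_edge_list(edges: pd.DataFrame, path: str | Path) -> None:
    out = edges.copy()
    out["score"] = out["score"].map(lambda s: f"{s:.2f}" if round(s, 2) == s else repr(float(s)))
    out.to_csv(Path(path), sep="\t", index=False)


def write_json(obj, path: str | Path) -> None:
    """Deterministic JSON writer used for ground truth, traces and results."""
    with open(Path(path), "w") as handle:
        json.dump(obj, handle, indent=2, sort_keys=True)
        handle.write("\n")


def read_json(path: str | Path):
    with open(Path(path)) as handle:
        return json.load(handle)
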