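"""Readers and writers for the package's plain-text formats.

All tabular files are tab-separated UTF-8 with a header row, "." as the
decimal mark, and Unix line endings on write (Windows endings accepted
on read).  Expression matrices carry gene IDs in the first column.
Gene sets use the standard GMT layout: one set per line — name,
description, then tab-separated member IDs.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .dataset import ANNOTATION_COLUMNS, DatasetError, ExpressionDataset


class FormatError(ValueError):
    """Raised for malformed input files, naming the offending location."""


# -- expression matrices ------------------------------------------------------

def read_matrix(path: str | os.PathLike) -> pd.DataFrame:
    """Read a gene × sample TSV matrix, validating shape and values.

    Values are parsed with the exact (round-trip) float parser, so
    ``write -> read -> write`` reproduces the file byte for byte.
    """
    with open(path, encoding="utf-8", newline=None) as fh:
        header = fh.readline().rstrip("\r\n").split("\t")
    samples = header[1:]
    seen: set[str] = set()
    for s in samples:
        if s in seen:
            raise FormatError(f"{path}: duplicate sample ID {s!r}")
        seen.add(s)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, header=0,
                     names=["gene_id"] + list(samples))
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate gene ID {dup!r}")
    columns = {}
    for col_pos, col in enumerate(df.columns):
        raw = df.iloc[:, col_pos]
        def _reject(row, cell):
            raise FormatError(
                f"{path}: non-numeric or missing cell at gene {row!r}, "
                f"sample {col!r} (value {cell!r}; ragged rows produce "
                f"missing cells)"
            )
        if raw.isna().any():
            bad = raw.index[raw.isna()][0]
            _reject(bad, None)
        try:
            parsed = raw.to_numpy(dtype=str).astype(float)
        except (ValueError, TypeError):
            for row, cell in zip(df.index, raw):
                try:
                    float(cell)
                except (ValueError, TypeError):
                    _reject(row, cell)
            raise
        if np.isnan(parsed).any():
            bad = raw.index[np.isnan(parsed)][0]
            _reject(bad, raw.loc[bad])
        columns[col] = parsed
    out = pd.DataFrame(columns, index=df.index)
    out.index.name = "gene_id"
    return out


def read_annotation(path: str | os.PathLike) -> pd.DataFrame:
    """Read a sample annotation TSV (sample_id, patient, tissue, disease, serum)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate sample ID {dup!r}")
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: annotation missing columns {missing}")
    return df


def read_expression(
    expr_path: str | os.PathLike, annot_path: str | os.PathLike
) -> ExpressionDataset:
    """Read matrix + annotation into an :class:`ExpressionDataset`."""
    values = read_matrix(expr_path)
    annot = read_annotation(annot_path)
    extra = [s for s in values.columns if s not in annot.index]
    if extra:
        raise FormatError(f"{annot_path}: no annotation for sample {extra[0]!r}")
    try:
        return ExpressionDataset(values, annot.loc[list(values.columns)])
    except DatasetError as exc:  # re-tag with file context
        raise FormatError(f"{expr_path}: {exc}") from exc


def write_table(obj: pd.DataFrame, path: str | os.PathLike, index: bool = True) -> None:
    """Write any DataFrame as TSV with Unix line endings, full precision."""
    obj.to_csv(path, sep="\t", index=index, lineterminator="\n")


def write_expression(dataset: ExpressionDataset, expr_path, annot_path) -> None:
    values = dataset.values.copy()
    values.index.name = "gene_id"
    write_table(values, expr_path)
    annot = dataset.annotation.copy()
    annot.index.name = "sample_id"
    write_table(annot, annot_path)


# -- GMT gene sets ------------------------------------------------------------

def read_gmt(path: str | os.PathLike) -> dict[str, list[str]]:
    """Read a GMT file into ``{set_name: [member, ...]}`` preserving order."""
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8", newline=None) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\r\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs name, description, >=1 member"
                )
            name, _desc, *members = fields
            members = [m for m in members if m]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = members
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | os.PathLike,
              description: str = "na") -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")


# -- ID mapping tables --------------------------------------------------------

def read_mapping(path: str | os.PathLike) -> pd.DataFrame:
    """Read a two-column (source_id, target_id) TSV; header required."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("source_id", "target_id"):
        if col not in df.columns:
            raise FormatError(f"{path}: mapping table must have a {col!r} column")
    return df[["source_id", "target_id"]]


# -- causal networks ----------------------------------------------------------

NETWORK_COLUMNS = ("gene_id", "function_id", "direction", "m_activating", "m_inhibiting")


def read_network(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "function_id": str})
    missing = [c for c in NETWORK_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: network table missing columns {missing}")
    return df[list(NETWORK_COLUMNS)]
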