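"""Readers and writers for the plain-text formats the pipeline exchanges.

Expression matrices travel as TSV with the feature id in the first column and
one column per sample; gene sets travel as GMT (name TAB description TAB
symbols...). Both round-trip losslessly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ParseError

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "read_gmt",
    "write_gmt",
    "read_json",
    "write_json",
]


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Read a feature x sample expression table.

    The first column holds feature ids (probesets or gene symbols), the
    header row holds sample ids, and the body must be numeric. Duplicated
    feature ids and ragged or non-numeric rows are rejected with the
    offending line number.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise ParseError(f"{path}: empty file", line=1)
        columns = header.split("\t")
        ncol = len(columns)
        ids: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != ncol:
                raise ParseError(
                    f"{path}: expected {ncol} fields, found {len(fields)}",
                    line=lineno,
                )
            ids.append(fields[0])
            try:
                rows.append([float(v) for v in fields[1:]])
            except ValueError as exc:
                raise ParseError(f"{path}: non-numeric cell ({exc})", line=lineno) from exc
    index = pd.Index(ids, name=columns[0])
    if index.has_duplicates:
        dups = sorted(index[index.duplicated()].unique())
        raise ParseError(f"{path}: duplicated feature ids: {', '.join(map(str, dups))}")
    return pd.DataFrame(np.asarray(rows, dtype=float), index=index, columns=columns[1:])


def write_expression_tsv(table: pd.DataFrame, path: str | Path) -> None:
    """Write a feature x sample table; inverse of :func:`read_expression_tsv`."""
    table = table.copy()
    table.index.name = table.index.name or "feature"
    # repr-round-trip float formatting keeps read(write(x)) == x bit-for-bit
    table.to_csv(path, sep="\t", float_format=None)


def read_gmt(path: str | Path) -> dict[str, tuple[str, list[str]]]:
    """Read a GMT file into ``{name: (description, [symbols...])}``.

    Symbol order is preserved. Lines with fewer than three tab-separated
    fields are rejected with their line number.
    """
    path = Path(path)
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}: GMT lines need name, description and >=1 symbol "
                    f"({len(fields)} fields found)",
                    line=lineno,
                )
            name, description, *symbols = fields
            if name in sets:
                raise ParseError(f"{path}: duplicated set name {name!r}", line=lineno)
            sets[name] = (description, symbols)
    return sets


def write_gmt(sets: dict[str, tuple[str, list[str]]], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, (description, symbols) in sets.items():
            fh.write("\t".join([name, description, *symbols]) + "\n")


def read_json(path: str | Path):
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)


def write_json(obj, path: str | Path) -> None:
    """Deterministic JSON: sorted keys, stable float repr, trailing newline."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")
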