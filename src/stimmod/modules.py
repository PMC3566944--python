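"""Signed gene modules.

A gene module is the ordered, signed list of the genes most changed by one
in vitro stimulus (TOP-N by fold change under an FDR gate). The sign of each
log2 fold change orients the gene when the module is projected onto cohort
data: positive entries rise with pathway activation, negative entries fall.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .exceptions import ParseError
from . import io as _io

__all__ = ["GeneModule", "read_module_tsv", "write_module_tsv"]


@dataclass(frozen=True)
class GeneModule:
    """An ordered signed gene list for one stimulus.

    Parameters
    ----------
    stimulus
        Label of the stimulus that defined the module (e.g. ``"aIgM"``).
    entries
        ``(symbol, log2fc)`` tuples sorted by signed log2fc ascending, the
        ordering used in printed module tables (strongest down-regulation
        first, strongest up-regulation last).
    n_max
        Selection size the module was built with (TOP-N).
    fdr_max
        BH-FDR gate applied before ranking by fold change.
    """

    stimulus: str
    entries: tuple[tuple[str, float], ...]
    n_max: int = 100
    fdr_max: float = 0.1
    warning: str | None = field(default=None, compare=False)

    def __post_init__(self):
        if len(self.entries) > self.n_max:
            raise ValueError(
                f"module {self.stimulus!r}: {len(self.entries)} entries exceed n_max={self.n_max}"
            )
        symbols = [s for s, _ in self.entries]
        if len(set(symbols)) != len(symbols):
            dups = sorted({s for s in symbols if symbols.count(s) > 1})
            raise ValueError(f"module {self.stimulus!r}: duplicated symbols {dups}")
        fcs = [fc for _, fc in self.entries]
        if any(a > b for a, b in zip(fcs, fcs[1:])):
            raise ValueError(f"module {self.stimulus!r}: entries not sorted by log2fc ascending")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def symbols(self) -> list[str]:
        return [s for s, _ in self.entries]

    @property
    def log2fc(self) -> pd.Series:
        return pd.Series(dict(self.entries), name="log2fc").reindex(self.symbols)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "module": self.stimulus,
                "rank": range(1, len(self.entries) + 1),
                "symbol": self.symbols,
                "log2fc": [fc for _, fc in self.entries],
            }
        )


def write_module_tsv(modules: list[GeneModule], path: str | Path) -> None:
    """Write modules as a long TSV (module, rank, symbol, log2fc)."""
    pd.concat([m.to_frame() for m in modules]).to_csv(path, sep="\t", index=False)


def read_module_tsv(path: str | Path, n_max: int = 100, fdr_max: float = 0.1) -> dict[str, GeneModule]:
    """Read modules from the long TSV written by :func:`write_module_tsv`."""
    path = Path(path)
    try:
        table = pd.read_csv(path, sep="\t", dtype={"module": str, "symbol": str})
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: {exc}") from exc
    required = {"module", "rank", "symbol", "log2fc"}
    if not required.issubset(table.columns):
        raise ParseError(f"{path}: missing columns {sorted(required - set(table.columns))}", line=1)
    modules: dict[str, GeneModule] = {}
    for name, block in table.groupby("module", sort=False):
        block = block.sort_values("rank")
        try:
            modules[name] = GeneModule(
                stimulus=str(name),
                entries=tuple(zip(block["symbol"], block["log2fc"].astype(float))),
                n_max=n_max,
                fdr_max=fdr_max,
            )
        except ValueError as exc:
            first = int(block.index.min()) + 2  # header + 0-based offset
            raise ParseError(f"{path}: {exc}", line=first) from exc
    return modules


def modules_to_gmt(modules: list[GeneModule]) -> dict[str, tuple[str, list[str]]]:
    return {
        m.stimulus: (f"TOP{m.n_max} genes, FDR<={m.fdr_max}", m.symbols) for m in modules
    }


def write_modules_gmt(modules: list[GeneModule], path: str | Path) -> None:
    _io.write_gmt(modules_to_gmt(modules), path)
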