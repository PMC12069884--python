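"""Allotetraploid homeolog collapsing and reciprocal symbol matching.

X. laevis carries duplicated gene copies on its long (.L) and short (.S)
chromosomes. For annotation transfer against diploid references the two
homeologs are collapsed by arithmetic mean (not sum — the collapsed output
is an expression matrix, never a count matrix, and count-based DE must not
consume it). Cross-species symbol transfer uses a reciprocal, case-
insensitive unique-match rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import pandas as pd
import scipy.sparse as sp

from .exceptions import HomeologAmbiguityError
from .io_qc import CountMatrix

__all__ = ["SymbolMap", "collapse_homeologs", "reciprocal_match"]

_SUFFIXES = (".L", ".S")  # literal, case-sensitive Xenopus nomenclature


def _base_symbol(symbol: str) -> str:
    for suf in _SUFFIXES:
        if symbol.endswith(suf):
            return symbol[: -len(suf)]
    return symbol


def collapse_homeologs(m: Union[CountMatrix, pd.DataFrame]) -> pd.DataFrame:
    """Average .L/.S homeolog rows into one row per base symbol.

    Rows whose identifier carries no suffix pass through unchanged; a base
    symbol with a single homeolog passes through under its base name. Three
    or more rows reducing to one base symbol raise
    :class:`HomeologAmbiguityError` listing the offenders.
    """
    if isinstance(m, CountMatrix):
        expr = m.to_frame().astype(float)
    else:
        expr = m.astype(float)
    base = expr.index.map(_base_symbol)
    sizes = pd.Series(1, index=expr.index).groupby(base).sum()
    bad = sizes[sizes > 2]
    if len(bad):
        offenders = {
            b: [g for g in expr.index if _base_symbol(g) == b] for b in bad.index
        }
        raise HomeologAmbiguityError(
            f"base symbols with more than two rows: {offenders}"
        )
    collapsed = expr.groupby(base, sort=False).mean()
    collapsed.index.name = expr.index.name
    return collapsed


@dataclass
class SymbolMap:
    """Bijective (on the mapped subset) cross-species symbol pairs."""

    pairs: pd.DataFrame  # columns: source, target
    unmapped_source: list[str] = field(default_factory=list)
    unmapped_target: list[str] = field(default_factory=list)
    direction: str = "source->target"

    def __post_init__(self) -> None:
        assert self.pairs["source"].is_unique and self.pairs["target"].is_unique

    def as_dict(self) -> dict[str, str]:
        return dict(zip(self.pairs["source"], self.pairs["target"]))

    def to_tsv(self, path: str | Path) -> None:
        self.pairs.to_csv(path, sep="\t", index=False)
        side = Path(path).with_suffix(".unmapped.txt")
        side.write_text("\n".join(self.unmapped_source) + ("\n" if self.unmapped_source else ""))


def reciprocal_match(
    source_symbols: Sequence[str], target_symbols: Sequence[str]
) -> SymbolMap:
    """Reciprocal case-insensitive unique symbol matching.

    A pair (a, b) is mapped iff lowercasing ``a`` matches exactly one target
    symbol ``b`` and lowercasing ``b`` matches exactly one source symbol,
    namely ``a``. Symbols ambiguous on either side, or without a
    counterpart, are reported unmapped.
    """
    source = list(dict.fromkeys(source_symbols))
    target = list(dict.fromkeys(target_symbols))
    src_by_lower: dict[str, list[str]] = {}
    for s in source:
        src_by_lower.setdefault(s.lower(), []).append(s)
    tgt_by_lower: dict[str, list[str]] = {}
    for t in target:
        tgt_by_lower.setdefault(t.lower(), []).append(t)

    pairs = []
    mapped_src, mapped_tgt = set(), set()
    for low, src_group in src_by_lower.items():
        tgt_group = tgt_by_lower.get(low, [])
        if len(src_group) == 1 and len(tgt_group) == 1:
            pairs.append((src_group[0], tgt_group[0]))
            mapped_src.add(src_group[0])
            mapped_tgt.add(tgt_group[0])
    return SymbolMap(
        pairs=pd.DataFrame(pairs, columns=["source", "target"]),
        unmapped_source=[s for s in source if s not in mapped_src],
        unmapped_target=[t for t in target if t not in mapped_tgt],
    )
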