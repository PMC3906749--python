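"""Curated gene-list handling: loading, canonicalization, screening.

Disease gene lists arrive from heterogeneous databases (human symbols in
upper case, stray whitespace, duplicate entries).  Everything here
normalizes them to mouse-style display symbols, restricts them to the
measured array background, screens list pairs for near-duplication, and
classifies symbols against a regulator catalog (transcription factors,
co-factors, chromatin remodeling factors).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TRANSCRIPTION_FACTOR = "transcription_factor"
CO_FACTOR = "co_factor"
CHROMATIN_REMODELING_FACTOR = "chromatin_remodeling_factor"
REGULATOR_CATEGORIES = (TRANSCRIPTION_FACTOR, CO_FACTOR, CHROMATIN_REMODELING_FACTOR)

NEAR_DUPLICATE_THRESHOLD = 0.8

__all__ = [
    "GeneSet",
    "GeneSetPanel",
    "RegulatorCatalog",
    "canonicalize_symbol",
    "load_gene_sets",
    "jaccard_similarity",
    "restrict_to_background",
    "classify_regulators",
    "read_gmt",
    "write_gmt",
    "REGULATOR_CATEGORIES",
    "TRANSCRIPTION_FACTOR",
    "CO_FACTOR",
    "CHROMATIN_REMODELING_FACTOR",
    "NEAR_DUPLICATE_THRESHOLD",
]


def canonicalize_symbol(raw: str) -> str:
    """Canonical display form of a gene symbol.

    Whitespace is trimmed and casing normalized to first-letter
    upper-case, remainder lower-case; digits and separators pass
    through, so ``"NKX2-1"`` becomes ``"Nkx2-1"``.  Matching anywhere in
    the package is on this canonical form, which makes human-database
    vs mouse-array comparison case-insensitive.
    """
    s = str(raw).strip()
    if not s:
        raise ValueError("empty gene symbol")
    return s[0].upper() + s[1:].lower()


@dataclass
class GeneSet:
    """A named, canonicalized, deduplicated gene list.

    ``category`` groups lists that probe the same disorder (used for the
    multi-list gene report); ``excluded_count`` and ``too_small`` are
    populated by :func:`restrict_to_background`.
    """

    name: str
    symbols: tuple[str, ...]
    source: str = ""
    category: str | None = None
    excluded_count: int = 0
    too_small: bool = False

    def __post_init__(self) -> None:
        seen: dict[str, None] = {}
        for s in self.symbols:
            seen.setdefault(canonicalize_symbol(s), None)
        dropped = len(self.symbols) - len(seen)
        if dropped:
            logger.info("gene set %s: collapsed %d duplicate entries", self.name, dropped)
        self.symbols = tuple(seen)

    def __len__(self) -> int:
        return len(self.symbols)

    @property
    def symbol_set(self) -> frozenset[str]:
        return frozenset(self.symbols)


@dataclass
class GeneSetPanel:
    """An ordered collection of gene sets with a pairwise Jaccard screen."""

    sets: list[GeneSet]
    near_duplicate_threshold: float = NEAR_DUPLICATE_THRESHOLD
    similarity: pd.DataFrame = field(init=False)
    flags: list[tuple[str, str]] = field(init=False)

    def __post_init__(self) -> None:
        names = [g.name for g in self.sets]
        if len(set(names)) != len(names):
            raise ValueError("gene set names must be unique within a panel")
        sim = np.eye(len(self.sets))
        flags: list[tuple[str, str]] = []
        for (i, a), (j, b) in itertools.combinations(enumerate(self.sets), 2):
            # background restriction can leave a set empty; similarity 0 then
            if not a.symbols or not b.symbols:
                continue
            sim[i, j] = sim[j, i] = jaccard_similarity(a, b)
            if sim[i, j] > self.near_duplicate_threshold:
                flags.append((a.name, b.name))
        self.similarity = pd.DataFrame(sim, index=names, columns=names)
        self.flags = flags

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def get(self, name: str) -> GeneSet:
        for g in self.sets:
            if g.name == name:
                return g
        raise KeyError(name)

    def report(self) -> pd.DataFrame:
        """Pairwise similarity report: columns pair, jaccard, flagged."""
        rows = []
        for (i, a), (j, b) in itertools.combinations(enumerate(self.sets), 2):
            rows.append(
                {
                    "pair": f"{a.name}|{b.name}",
                    "jaccard": self.similarity.iloc[i, j],
                    "flagged": (a.name, b.name) in self.flags,
                }
            )
        return pd.DataFrame(rows, columns=["pair", "jaccard", "flagged"])

    def restricted(self, background: Iterable[str]) -> "GeneSetPanel":
        """A new panel with every set restricted to the background."""
        bg = frozenset(background)
        return GeneSetPanel(
            [restrict_to_background(g, bg) for g in self.sets],
            self.near_duplicate_threshold,
        )


def jaccard_similarity(a: GeneSet, b: GeneSet) -> float:
    """|a n b| / |a u b| on the canonicalized symbol sets."""
    sa, sb = a.symbol_set, b.symbol_set
    if not sa or not sb:
        raise ValueError("jaccard_similarity requires non-empty sets")
    return len(sa & sb) / len(sa | sb)


def restrict_to_background(gene_set: GeneSet, background: Iterable[str]) -> GeneSet:
    """Intersect a list with the measured background.

    List genes absent from the array cannot be matched and must not
    inflate the list size used by the enrichment null.  An empty
    intersection is returned (flagged ``too_small``) rather than raised;
    the enrichment stage refuses such lists with an "excluded (too
    small)" note.
    """
    bg = frozenset(canonicalize_symbol(s) for s in background)
    if not bg:
        raise ValueError("background is empty")
    kept = tuple(s for s in gene_set.symbols if s in bg)
    excluded = len(gene_set.symbols) - len(kept)
    if not kept:
        logger.warning("gene set %s: empty after background restriction", gene_set.name)
    return GeneSet(
        name=gene_set.name,
        symbols=kept,
        source=gene_set.source,
        category=gene_set.category,
        excluded_count=excluded,
        too_small=not kept,
    )


def _load_txt(path: Path) -> GeneSet:
    symbols = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        s = line.strip()
        if not s or s.startswith("#"):
            continue
        try:
            symbols.append(canonicalize_symbol(s))
        except ValueError as exc:  # pragma: no cover - defensive
            raise ValueError(f"{path}:{lineno}: {exc}") from exc
    if not symbols:
        raise ValueError(f"{path}: no gene symbols found")
    return GeneSet(name=path.stem, symbols=tuple(symbols), source=str(path))


def read_gmt(path) -> list[GeneSet]:
    """Read a GMT file (tab-separated: name, description, symbols...)."""
    path = Path(path)
    sets = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: GMT rows need name, description, >=1 symbol")
        name, desc, *symbols = fields
        symbols = [s for s in symbols if s.strip()]
        if not symbols:
            raise ValueError(f"{path}:{lineno}: gene set {name!r} is empty")
        sets.append(GeneSet(name=name, symbols=tuple(symbols), source=desc))
    if not sets:
        raise ValueError(f"{path}: no gene sets found")
    return sets


def write_gmt(sets: Sequence[GeneSet], path) -> None:
    lines = ["\t".join([g.name, g.source or g.name, *g.symbols]) for g in sets]
    Path(path).write_text("\n".join(lines) + "\n")


def load_gene_sets(paths: Sequence, fmt: str | None = None) -> GeneSetPanel:
    """Load one-symbol-per-line txt files and/or GMT files into a panel.

    ``fmt`` forces a format; by default it is inferred per file from the
    extension (``.gmt`` vs anything else = txt).
    """
    sets: list[GeneSet] = []
    for p in paths:
        p = Path(p)
        kind = fmt or ("gmt" if p.suffix.lower() == ".gmt" else "txt")
        if kind == "gmt":
            sets.extend(read_gmt(p))
        elif kind == "txt":
            sets.append(_load_txt(p))
        else:
            raise ValueError(f"unknown gene list format {kind!r}")
    return GeneSetPanel(sets)


class RegulatorCatalog:
    """symbol -> regulator category map (one category per symbol)."""

    def __init__(self, mapping: Mapping[str, str]):
        self._map: dict[str, str] = {}
        for sym, cat in mapping.items():
            if cat not in REGULATOR_CATEGORIES:
                raise ValueError(f"unknown regulator category {cat!r} for {sym!r}")
            self._map[canonicalize_symbol(sym)] = cat

    def __len__(self) -> int:
        return len(self._map)

    def __contains__(self, symbol: str) -> bool:
        return canonicalize_symbol(symbol) in self._map

    def category(self, symbol: str) -> str | None:
        return self._map.get(canonicalize_symbol(symbol))

    def symbols(self) -> frozenset[str]:
        return frozenset(self._map)

    def items(self):
        return self._map.items()

    @classmethod
    def from_tsv(cls, path) -> "RegulatorCatalog":
        df = pd.read_csv(path, sep="\t")
        return cls(dict(zip(df["symbol"].astype(str), df["category"].astype(str))))

    def to_tsv(self, path) -> None:
        pd.DataFrame(sorted(self._map.items()), columns=["symbol", "category"]).to_csv(
            path, sep="\t", index=False
        )


def classify_regulators(
    symbols: Iterable[str], catalog: RegulatorCatalog
) -> dict[str, list[str]]:
    """Partition symbols by regulator category.

    Returns a dict with one sorted list per category plus
    ``"unclassified"`` for symbols absent from the catalog; the lists
    partition the (canonicalized, deduplicated) input.
    """
    out: dict[str, list[str]] = {cat: [] for cat in REGULATOR_CATEGORIES}
    out["unclassified"] = []
    for sym in sorted({canonicalize_symbol(s) for s in symbols}):
        out[catalog.category(sym) or "unclassified"].append(sym)
    return out
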