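"""Parsing, normalization and comparison of gene lists and ranked results.

Two kinds of input feed an enrichment run:

* a *gene list of interest* — one symbol per line, the curated disease
  "database" whose overrepresentation is tested;
* *ranked expression results* — a tab-separated file with one row per
  platform target (probe set), ordered by significance, carrying the target
  id and an optional gene-symbol annotation.

From the ranked results two derived views are built: the *background* (all
annotated targets, duplicate probes for a gene retained so the gene keeps its
platform weight) and the *significant gene list* (the top-``n`` unique
annotated genes, each represented once).

Symbols are matched exactly after normalization (uppercase, stripped); no
alias or ortholog resolution is attempted.
"""

from __future__ import annotations

import csv
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("mset")

#: Sentinel for a missing gene-symbol annotation on a platform target.
ABSENT = None

#: Symbol-field values treated as "no annotation" (after stripping), besides
#: the empty string. Configurable per call.
DEFAULT_NA_SENTINELS = frozenset({"---", "NA", "N/A", "NULL"})

_HEADER_TOKENS = {
    "probe", "probe_id", "probeid", "probe set id", "probeset", "id",
    "target", "target_id", "symbol", "gene", "gene_symbol", "genesymbol",
    "gene symbol", "gene_id",
}


def normalize_symbol(raw: str) -> str:
    """Normalize a gene symbol: strip surrounding whitespace, uppercase.

    Raises ``ValueError`` for symbols that are empty after stripping or that
    contain tabs/newlines (they cannot round-trip through the text formats).
    """
    sym = raw.strip().upper()
    if not sym:
        raise ValueError("empty gene symbol")
    if "\t" in sym or "\n" in sym or "\r" in sym:
        raise ValueError(f"gene symbol contains tab/newline: {raw!r}")
    return sym


def _is_annotated(field_value: str, na_sentinels: frozenset[str]) -> bool:
    v = field_value.strip()
    return bool(v) and v.upper() not in na_sentinels


@dataclass(frozen=True)
class GeneSet:
    """A named, deduplicated set of normalized gene symbols."""

    name: str
    symbols: frozenset[str]
    source_path: str | None = None

    def __post_init__(self) -> None:
        if not self.symbols:
            raise ValueError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.symbols)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.symbols

    @classmethod
    def from_symbols(
        cls, symbols: Iterable[str], name: str, source_path: str | None = None
    ) -> "GeneSet":
        """Build a set from raw symbols, normalizing and deduplicating."""
        normalized = frozenset(normalize_symbol(s) for s in symbols)
        return cls(name=name, symbols=normalized, source_path=source_path)


@dataclass(frozen=True)
class RankedRecord:
    """One platform target in the significance-ordered results.

    ``symbol`` is ``None`` (ABSENT) when the target has no gene annotation.
    ``rank`` is the 1-based position in the file, i.e. significance order.
    """

    probe_id: str
    symbol: str | None
    rank: int

    def __post_init__(self) -> None:
        if not self.probe_id:
            raise ValueError("probe_id must be non-empty")
        if self.rank < 1:
            raise ValueError("rank must be >= 1")


class Background:
    """The platform universe: all annotated targets, probe multiplicity kept.

    A gene measured by several probe sets appears once per probe set, which
    is what gives it extra weight when null results are sampled from the
    background.
    """

    def __init__(self, records: Sequence[RankedRecord]):
        if not records:
            raise ValueError("background has no annotated records")
        if any(r.symbol is None for r in records):
            raise ValueError("background records must all carry a symbol")
        self.records: tuple[RankedRecord, ...] = tuple(records)
        # integer gene codes for fast sampling
        symbols = [r.symbol for r in self.records]
        self.unique_genes: tuple[str, ...] = tuple(dict.fromkeys(symbols))
        index = {g: i for i, g in enumerate(self.unique_genes)}
        self.gene_codes: np.ndarray = np.fromiter(
            (index[s] for s in symbols), dtype=np.int64, count=len(symbols)
        )
        self._index = index

    @property
    def n_targets(self) -> int:
        return len(self.records)

    @property
    def n_unique_genes(self) -> int:
        return len(self.unique_genes)

    @property
    def is_duplicate_free(self) -> bool:
        return self.n_targets == self.n_unique_genes

    def multiplicity(self) -> Counter:
        """Probe count per gene symbol."""
        return Counter(r.symbol for r in self.records)

    def membership_mask(self, gene_set: GeneSet) -> np.ndarray:
        """Boolean mask over gene codes: is unique gene i in ``gene_set``."""
        return np.fromiter(
            (g in gene_set.symbols for g in self.unique_genes),
            dtype=bool,
            count=self.n_unique_genes,
        )

    @classmethod
    def from_symbols(cls, symbols: Sequence[str]) -> "Background":
        """Convenience constructor from bare symbols (one per target)."""
        records = [
            RankedRecord(probe_id=f"t{i + 1}", symbol=normalize_symbol(s), rank=i + 1)
            for i, s in enumerate(symbols)
        ]
        return cls(records)


@dataclass(frozen=True)
class SignificantGeneList:
    """The top-``L`` unique annotated genes of the ranked results."""

    symbols: tuple[str, ...]
    threshold_mode: str = "unique_genes"

    def __post_init__(self) -> None:
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError("significant gene list contains duplicates")
        if self.threshold_mode not in ("unique_genes", "raw_rows"):
            raise ValueError(f"unknown threshold mode {self.threshold_mode!r}")

    @property
    def L(self) -> int:
        return len(self.symbols)

    def __len__(self) -> int:
        return len(self.symbols)

    def __iter__(self):
        return iter(self.symbols)


def load_gene_set(path: str | Path, name: str | None = None) -> GeneSet:
    """Load a gene list of interest: one symbol per line.

    Blank lines and ``#`` comment lines are ignored; symbols are normalized
    (stripped, uppercased) and deduplicated. Raises ``ValueError`` when no
    valid symbol survives.
    """
    path = Path(path)
    raw_lines = 0
    symbols: list[str] = []
    with path.open("r", encoding="utf-8") as fh:
        for line in fh:
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            raw_lines += 1
            symbols.append(normalize_symbol(stripped))
    if not symbols:
        raise ValueError(f"no gene symbols found in {path}")
    unique = frozenset(symbols)
    logger.info(
        "loaded gene set %s from %s: %d lines, %d unique symbols",
        name or path.stem, path, raw_lines, len(unique),
    )
    return GeneSet(name=name or path.stem, symbols=unique, source_path=str(path))


def load_ranked_results(
    path: str | Path, na_sentinels: Iterable[str] = DEFAULT_NA_SENTINELS
) -> list[RankedRecord]:
    """Load significance-ordered results from a 2+-column TSV.

    Column 1 is the target/probe id, column 2 the gene symbol (may be empty
    or a sentinel such as ``---``; extra columns are ignored). Rank is the
    1-based file position — the file is trusted to be ordered by
    significance. An optional single header row is auto-detected. Targets
    without annotation are kept at this stage (symbol = ABSENT).
    """
    path = Path(path)
    na = frozenset(s.strip().upper() for s in na_sentinels)
    records: list[RankedRecord] = []
    n_absent = 0
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        rank = 0
        for i, row in enumerate(reader):
            if not row or not "".join(row).strip():
                continue
            probe = row[0].strip()
            sym_field = row[1] if len(row) > 1 else ""
            if i == 0 and (
                probe.lower() in _HEADER_TOKENS
                or sym_field.strip().lower() in _HEADER_TOKENS
            ):
                continue
            rank += 1
            if _is_annotated(sym_field, na):
                symbol: str | None = normalize_symbol(sym_field)
            else:
                symbol = ABSENT
                n_absent += 1
            records.append(RankedRecord(probe_id=probe, symbol=symbol, rank=rank))
    if not records:
        raise ValueError(f"no records found in ranked results file {path}")
    logger.info(
        "loaded ranked results %s: %d targets, %d without gene annotation",
        path, len(records), n_absent,
    )
    return records


def prepare_background(records: Sequence[RankedRecord]) -> Background:
    """Build the sampling background: drop unannotated targets, keep dupes.

    Relative order and per-gene probe multiplicity are preserved — the
    multiplicity is exactly what weights each gene in the null.
    """
    annotated = [r for r in records if r.symbol is not None]
    if not annotated:
        raise ValueError("no annotated records: background would be empty")
    bg = Background(annotated)
    logger.info(
        "background: %d annotated targets, %d unique genes (%d dropped)",
        bg.n_targets, bg.n_unique_genes, len(records) - bg.n_targets,
    )
    return bg


def prepare_significant_results(
    records: Sequence[RankedRecord],
    n_top: int,
    mode: str = "unique_genes",
) -> SignificantGeneList:
    """Select the top significant genes, one entry per gene.

    ``unique_genes`` mode (default) scans down the ranking until ``n_top``
    distinct annotated genes are collected, so ``L == n_top`` exactly.
    ``raw_rows`` mode takes the first ``n_top`` rows and then removes
    unannotated targets and duplicate genes, so ``L <= n_top``. Either way a
    duplicated gene keeps its best (earliest) rank.
    """
    if n_top < 1:
        raise ValueError("n_top must be >= 1")
    if mode not in ("unique_genes", "raw_rows"):
        raise ValueError(f"unknown threshold mode {mode!r}")

    seen: dict[str, None] = {}
    if mode == "unique_genes":
        for r in records:
            if r.symbol is None or r.symbol in seen:
                continue
            seen[r.symbol] = None
            if len(seen) == n_top:
                break
        if len(seen) < n_top:
            raise ValueError(
                f"requested {n_top} unique annotated genes but only "
                f"{len(seen)} are available"
            )
    else:
        for r in records[:n_top]:
            if r.symbol is None or r.symbol in seen:
                continue
            seen[r.symbol] = None
        if not seen:
            raise ValueError(
                f"first {n_top} rows contain no annotated genes"
            )
    symbols = tuple(seen)
    logger.info(
        "significant list (%s, n_top=%d): L=%d unique genes",
        mode, n_top, len(symbols),
    )
    return SignificantGeneList(symbols=symbols, threshold_mode=mode)


def pairwise_redundancy(a: GeneSet, b: GeneSet) -> float:
    """Redundancy of two gene lists.

    The proportion of the smaller list that is identical to (shared with)
    the larger list: ``|a & b| / min(|a|, |b|)``. Symmetric; 1.0 when one
    list is contained in the other, 0.0 when disjoint.
    """
    if not a.symbols or not b.symbols:
        raise ValueError("redundancy undefined for empty gene sets")
    inter = len(a.symbols & b.symbols)
    return inter / min(len(a.symbols), len(b.symbols))


def redundancy_matrix(sets: Sequence[GeneSet]) -> pd.DataFrame:
    """Pairwise redundancy matrix over gene lists.

    Returns a symmetric DataFrame with unit diagonal, indexed by set name
    in input order.
    """
    if len(sets) < 2:
        raise ValueError("need at least two gene sets")
    names = [s.name for s in sets]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate gene set names: {names}")
    n = len(sets)
    mat = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = pairwise_redundancy(sets[i], sets[j])
    return pd.DataFrame(mat, index=names, columns=names)
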