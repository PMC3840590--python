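"""The randomization engine: platform-weighted null, match counts, p-value.

A simulated result is built by drawing targets (probe sets) without
replacement from the background, so a gene covered by several probes has a
proportionally greater chance of entering the simulated list — the null is
weighted true-to-platform. Operationally, each simulated result draws twice
the length of the real significant list, removes duplicate genes keeping the
first occurrence, truncates to the first ``L`` unique genes, and tops up with
further single draws in the rare case the doubled draw held fewer than ``L``
distinct genes. That procedure is exactly equivalent to taking the first
``L`` unique genes along a uniform random permutation of the background
targets, which is how the vectorised sampler implements it.

The empirical p-value is the proportion of simulated results containing at
least as many gene-list matches as the observed significant results.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .genelist_io import (
    Background,
    GeneSet,
    RankedRecord,
    SignificantGeneList,
    prepare_background,
    prepare_significant_results,
)

logger = logging.getLogger("mset")

#: Fixed number of simulations per internal RNG chunk. Each chunk's generator
#: is derived from (seed, chunk index), so results for a given seed do not
#: depend on how many simulations are requested in total.
_CHUNK_SIMS = 4096

#: Soft floor below which a warning about Monte-Carlo resolution is emitted.
_MIN_SIMS_WARN = 1000
#: Hard minimum number of simulated results.
_MIN_SIMS = 100


@dataclass(frozen=True)
class NullDistribution:
    """Histogram of match counts over simulated results."""

    counts: dict[int, int]
    n_sims: int

    def __post_init__(self) -> None:
        if self.n_sims < 1:
            raise ValueError("n_sims must be >= 1")
        if any(k < 0 for k in self.counts):
            raise ValueError("match counts must be non-negative")
        if sum(self.counts.values()) != self.n_sims:
            raise ValueError("null histogram mass does not equal n_sims")

    @classmethod
    def from_match_counts(cls, matches: np.ndarray) -> "NullDistribution":
        ks, ns = np.unique(np.asarray(matches, dtype=np.int64), return_counts=True)
        return cls(
            counts={int(k): int(n) for k, n in zip(ks, ns)},
            n_sims=int(len(matches)),
        )

    @property
    def max_matches(self) -> int:
        return max(self.counts) if self.counts else 0

    def pmf(self) -> dict[int, float]:
        """Probability of exactly k matches in a simulated result."""
        return {k: n / self.n_sims for k, n in sorted(self.counts.items())}

    def survival(self, observed: int) -> float:
        """P(matches >= observed) under the simulated null."""
        tail = sum(n for k, n in self.counts.items() if k >= observed)
        return tail / self.n_sims


@dataclass(frozen=True)
class EnrichmentResult:
    """Complete outcome of one enrichment test."""

    database_name: str
    dataset_name: str
    observed_matches: int
    matched_genes: tuple[str, ...]
    p_value: float
    null: NullDistribution
    L: int
    n_sims: int
    seed: int
    n_top: int
    threshold_mode: str = "unique_genes"
    background_n_targets: int = 0
    background_n_unique_genes: int = 0
    gene_set_size: int = 0

    def __post_init__(self) -> None:
        if self.observed_matches != len(self.matched_genes):
            raise ValueError("observed_matches must equal roster size")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value outside [0, 1]")

    def p_value_display(self) -> str:
        """p-value string with the Monte-Carlo resolution floor made explicit."""
        if self.p_value == 0.0:
            return f"< {1 / self.n_sims:g}"
        return f"{self.p_value:g}"

    def to_dict(self) -> dict:
        return {
            "database_name": self.database_name,
            "dataset_name": self.dataset_name,
            "observed_matches": self.observed_matches,
            "matched_genes": list(self.matched_genes),
            "p_value": self.p_value,
            "p_value_display": self.p_value_display(),
            "L": self.L,
            "n_sims": self.n_sims,
            "seed": self.seed,
            "n_top": self.n_top,
            "threshold_mode": self.threshold_mode,
            "background_n_targets": self.background_n_targets,
            "background_n_unique_genes": self.background_n_unique_genes,
            "gene_set_size": self.gene_set_size,
            "null_histogram": {str(k): v for k, v in sorted(self.null.counts.items())},
        }

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("indent", 2)
        kwargs.setdefault("sort_keys", True)
        return json.dumps(self.to_dict(), **kwargs)


def count_matches(
    genes: Sequence[str], target_set: GeneSet
) -> tuple[int, tuple[str, ...]]:
    """Count genes present in the gene list of interest.

    Returns the number of matches and the matched roster in input order.
    ``genes`` is expected to be duplicate-free (a significant or simulated
    result list).
    """
    roster = tuple(g for g in genes if g in target_set.symbols)
    return len(roster), roster


def sample_simulated_results(
    background: Background, L: int, rng: np.random.Generator
) -> tuple[str, ...]:
    """Draw one simulated result of ``L`` unique genes from the background.

    Targets are sampled without replacement; duplicate genes are collapsed
    keeping the first occurrence and the list is truncated to the first
    ``L`` unique genes, topping up with further draws if the initial ``2L``
    targets held fewer than ``L`` distinct genes.
    """
    _check_draw(background, L)
    seen: dict[str, None] = {}
    for t in rng.permutation(background.n_targets):
        sym = background.records[t].symbol
        if sym not in seen:
            seen[sym] = None
            if len(seen) == L:
                break
    return tuple(seen)


def _check_draw(background: Background, L: int) -> None:
    if L < 1:
        raise ValueError("L must be >= 1")
    if background.n_unique_genes < L:
        raise ValueError(
            f"background holds only {background.n_unique_genes} unique genes; "
            f"cannot build simulated results of length {L}"
        )
    if 2 * L > background.n_targets:
        logger.info(
            "doubled draw (2L=%d) exceeds background size (%d); "
            "sampling sequentially until %d unique genes",
            2 * L, background.n_targets, L,
        )


def _chunk_rngs(seed: int, n_sims: int) -> list[np.random.Generator]:
    n_chunks = (n_sims + _CHUNK_SIMS - 1) // _CHUNK_SIMS
    children = np.random.SeedSequence(seed).spawn(n_chunks)
    return [np.random.default_rng(c) for c in children]


def simulate_match_counts(
    background: Background,
    L: int,
    target_set: GeneSet,
    n_sims: int,
    seed: int,
) -> np.ndarray:
    """Match counts of ``n_sims`` independent simulated results.

    Vectorised over simulations; bit-reproducible for a given seed.
    """
    _check_draw(background, L)
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    n = background.n_targets
    mask = background.membership_mask(target_set)
    codes = background.gene_codes
    out = np.empty(n_sims, dtype=np.int64)
    pos = 0
    for rng in _chunk_rngs(seed, n_sims):
        b = min(_CHUNK_SIMS, n_sims - pos)
        keys = rng.random((b, n))
        if background.is_duplicate_free:
            out[pos:pos + b] = _counts_duplicate_free(keys, codes, mask, L)
        else:
            out[pos:pos + b] = _counts_weighted(keys, codes, mask, L)
        pos += b
    return out


def _counts_duplicate_free(
    keys: np.ndarray, codes: np.ndarray, mask: np.ndarray, L: int
) -> np.ndarray:
    # One probe per gene: the simulated result is a uniform L-subset, and
    # only membership matters, so the within-draw ordering can be skipped.
    n = keys.shape[1]
    if L == n:
        return np.full(keys.shape[0], int(mask[codes].sum()), dtype=np.int64)
    idx = np.argpartition(keys, L - 1, axis=1)[:, :L]
    return mask[codes[idx]].sum(axis=1)


def _counts_weighted(
    keys: np.ndarray, codes: np.ndarray, mask: np.ndarray, L: int
) -> np.ndarray:
    b, n = keys.shape
    m = min(2 * L, n)
    if m < n:
        part = np.argpartition(keys, m - 1, axis=1)[:, :m]
    else:
        part = np.broadcast_to(np.arange(n), (b, n))
    pk = np.take_along_axis(keys, part, axis=1)
    order = np.argsort(pk, axis=1, kind="stable")
    drawn = np.take_along_axis(part, order, axis=1)  # first m draws, in order
    g = codes[drawn]

    # first occurrence of each gene within the draw, via stable sort
    s = np.argsort(g, axis=1, kind="stable")
    gs = np.take_along_axis(g, s, axis=1)
    dup_sorted = np.concatenate(
        [np.zeros((b, 1), dtype=bool), gs[:, 1:] == gs[:, :-1]], axis=1
    )
    dup = np.empty_like(dup_sorted)
    np.put_along_axis(dup, s, dup_sorted, axis=1)
    first = ~dup
    cum = np.cumsum(first, axis=1)
    kept = first & (cum <= L)
    counts = (kept & mask[g]).sum(axis=1).astype(np.int64)

    # top-up: rows whose 2L draw held < L distinct genes continue drawing
    short_rows = np.nonzero(cum[:, -1] < L)[0]
    for r in short_rows:
        full_order = np.argsort(keys[r], kind="stable")
        seen: dict[int, None] = {}
        for t in full_order:
            c = int(codes[t])
            if c not in seen:
                seen[c] = None
                if len(seen) == L:
                    break
        counts[r] = sum(mask[c] for c in seen)
    return counts


def build_null(
    background: Background,
    L: int,
    target_set: GeneSet,
    n_sims: int,
    seed: int,
) -> NullDistribution:
    """Simulated null distribution of matches to the gene list of interest."""
    if n_sims < _MIN_SIMS:
        raise ValueError(f"n_sims must be >= {_MIN_SIMS}")
    if n_sims < _MIN_SIMS_WARN:
        logger.warning(
            "n_sims=%d gives a coarse p-value resolution of %.3g",
            n_sims, 1 / n_sims,
        )
    matches = simulate_match_counts(background, L, target_set, n_sims, seed)
    return NullDistribution.from_match_counts(matches)


def empirical_p(null: NullDistribution, observed: int) -> float:
    """Proportion of simulated results with at least ``observed`` matches.

    Zero is stored as 0.0; display layers render it as "< 1/n_sims".
    """
    if observed < 0:
        raise ValueError("observed match count must be >= 0")
    return null.survival(observed)


def run_mset(
    records: Sequence[RankedRecord],
    target_set: GeneSet,
    n_top: int,
    n_sims: int = 10_000,
    seed: int = 0,
    mode: str = "unique_genes",
    dataset_name: str = "dataset",
) -> EnrichmentResult:
    """Run the full enrichment test on significance-ordered results.

    Composes background preparation, top-gene selection, observed match
    counting, null simulation and the empirical tail p-value. All run
    parameters and the matched-gene roster are recorded on the result.
    """
    background = prepare_background(records)
    significant = prepare_significant_results(records, n_top, mode=mode)
    observed, roster = count_matches(significant.symbols, target_set)
    null = build_null(background, significant.L, target_set, n_sims, seed)
    p = empirical_p(null, observed)
    logger.info(
        "MSET %s vs %s: observed=%d of L=%d, p=%s",
        target_set.name, dataset_name, observed, significant.L,
        f"{p:g}" if p > 0 else f"< {1 / n_sims:g}",
    )
    return EnrichmentResult(
        database_name=target_set.name,
        dataset_name=dataset_name,
        observed_matches=observed,
        matched_genes=roster,
        p_value=p,
        null=null,
        L=significant.L,
        n_sims=n_sims,
        seed=seed,
        n_top=n_top,
        threshold_mode=mode,
        background_n_targets=background.n_targets,
        background_n_unique_genes=background.n_unique_genes,
        gene_set_size=len(target_set),
    )
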