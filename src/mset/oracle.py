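"""Independent exact computations for validating the randomization engine.

When every background gene is covered by exactly one probe, the simulated
null is exactly hypergeometric: the number of gene-list members in a uniform
draw of ``L`` genes from ``N``. For weighted backgrounds (duplicate probes)
there is no closed form; small instances are enumerated exactly over the
sequential draw process, with exact rational arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache

from scipy.stats import hypergeom

from .genelist_io import Background, GeneSet

#: Largest weighted background (in targets) the enumerator will attempt.
MAX_ENUMERABLE_TARGETS = 15


@dataclass(frozen=True)
class HypergeomSpec:
    """Parameters of a hypergeometric tail query.

    N unique background genes, K of which belong to the gene list of
    interest; n genes drawn (the significant-list length L); k observed
    matches.
    """

    N: int
    K: int
    n: int
    k: int

    def __post_init__(self) -> None:
        if not 0 <= self.K <= self.N:
            raise ValueError("need 0 <= K <= N")
        if not 0 <= self.n <= self.N:
            raise ValueError("need 0 <= n <= N")
        if not 0 <= self.k <= min(self.n, self.K):
            raise ValueError("need 0 <= k <= min(n, K)")


def hypergeom_tail(spec: HypergeomSpec) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if spec.k == 0:
        return 1.0
    return float(hypergeom.sf(spec.k - 1, spec.N, spec.K, spec.n))


def brute_force_null(
    background: Background,
    L: int,
    target_set: GeneSet,
    max_targets: int = MAX_ENUMERABLE_TARGETS,
) -> dict[int, float]:
    """Exact match-count distribution implied by the sampling scheme.

    Enumerates every sequential without-replacement draw of targets,
    collecting unique genes until ``L`` are held (identical semantics to the
    engine's doubled-draw/dedupe/top-up procedure). Duplicate-free
    backgrounds use the hypergeometric closed form directly. Returns
    probabilities keyed by match count.
    """
    if L < 1 or background.n_unique_genes < L:
        raise ValueError("need 1 <= L <= number of unique background genes")

    if background.is_duplicate_free:
        N = background.n_unique_genes
        K = int(background.membership_mask(target_set).sum())
        dist = {
            k: float(hypergeom.pmf(k, N, K, L))
            for k in range(max(0, L + K - N), min(L, K) + 1)
        }
        return {k: p for k, p in dist.items() if p > 0.0}

    if background.n_targets > max_targets:
        raise ValueError(
            f"background of {background.n_targets} targets too large to "
            f"enumerate (limit {max_targets})"
        )

    mult = background.multiplicity()
    in_target = {g: g in target_set.symbols for g in mult}
    # genes with identical (remaining probes, target flag, collected) are
    # exchangeable; states are canonicalised as sorted count tuples
    start = tuple(sorted((mult[g], in_target[g], False) for g in mult))

    @lru_cache(maxsize=None)
    def walk(classes: tuple, collected: int, matched: int) -> tuple:
        if collected == L:
            return ((matched, Fraction(1)),)
        total = sum(r for r, _, _ in classes)
        if total == 0:
            return ((matched, Fraction(1)),)
        acc: dict[int, Fraction] = {}
        groups: dict[tuple, int] = {}
        for cls in classes:
            groups[cls] = groups.get(cls, 0) + 1
        for (r, flag, done), g_count in groups.items():
            p = Fraction(r * g_count, total)
            nxt = list(classes)
            nxt.remove((r, flag, done))
            if r > 1:
                nxt.append((r - 1, flag, True))
            sub = walk(
                tuple(sorted(nxt)),
                collected + (0 if done else 1),
                matched + (1 if (flag and not done) else 0),
            )
            for k, q in sub:
                acc[k] = acc.get(k, Fraction(0)) + p * q
        return tuple(sorted(acc.items()))

    result = walk(start, 0, 0)
    walk.cache_clear()
    return {k: float(p) for k, p in result}
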