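"""Replicated validation experiments for the randomization engine.

These are the package's own correctness experiments, exercised by the test
suite and by ``scripts/acceptance.py``:

* agreement of the empirical p-value with the exact hypergeometric tail on
  duplicate-free backgrounds;
* agreement of the weighted (multi-probe) null with exact enumeration on
  small instances;
* type-I-error calibration under random gene lists;
* power as a function of planted overlap;
* specificity on a 2x2 crossed design.

Every function takes a single integer seed and derives all internal
randomness from it deterministically.
"""

from __future__ import annotations

import hashlib
import statistics
from typing import Sequence

import numpy as np

from .core import build_null, count_matches, empirical_p, run_mset, simulate_match_counts
from .genelist_io import Background, GeneSet, load_gene_set, load_ranked_results
from .oracle import HypergeomSpec, brute_force_null, hypergeom_tail
from .synthetic import SyntheticSpec, generate_dataset, generate_specificity_design


def derive_seed(root: int, *labels) -> int:
    """Deterministic child seed from a root seed and string labels.

    Used for batch cells and replicate experiments so that adding a cell or
    replicate never perturbs the others. Result is below 2**31.
    """
    digest = hashlib.sha256(
        "\x1f".join(str(x) for x in labels).encode("utf-8")
    ).digest()
    entropy = int.from_bytes(digest[:8], "little")
    return int(np.random.SeedSequence([root, entropy]).generate_state(1)[0]) % (2**31)


def _uniform_background(n_genes: int) -> Background:
    return Background.from_symbols([f"G{i:05d}" for i in range(1, n_genes + 1)])


# ---------------------------------------------------------------------------
# hypergeometric oracle agreement (duplicate-free backgrounds)

#: (N, K/N, L/N-ish) grid spanning small to platform-sized backgrounds.
ORACLE_CONFIGS: tuple[tuple[int, float, int], ...] = tuple(
    (int(n), kf, int(np.clip(round(lf * int(n)), 5, min(500, int(n)))))
    for n, kf, lf in zip(
        np.geomspace(50, 5000, 20).round(),
        [0.01, 0.05, 0.1, 0.2, 0.3, 0.5] * 4,
        [0.1, 0.3, 0.05, 0.2, 0.5] * 4,
    )
)


def oracle_agreement_sweep(seed: int, n_sims: int = 100_000) -> dict:
    """Empirical tail p vs exact hypergeometric tail over the config grid.

    For each duplicate-free configuration the observed count is set at the
    null mean, where the tail probability is moderate and the binomial
    standard error is informative. Returns per-config records and the
    fraction of configs agreeing within three standard errors.
    """
    records = []
    for i, (N, k_frac, L) in enumerate(ORACLE_CONFIGS):
        K = max(1, round(k_frac * N))
        bg = _uniform_background(N)
        target = GeneSet.from_symbols(bg.unique_genes[:K], name=f"set{i}")
        k_obs = max(1, round(L * K / N))
        p_true = hypergeom_tail(HypergeomSpec(N=N, K=K, n=L, k=k_obs))
        counts = simulate_match_counts(
            bg, L, target, n_sims, derive_seed(seed, "oracle", i)
        )
        p_emp = float(np.mean(counts >= k_obs))
        se = float(np.sqrt(p_true * (1.0 - p_true) / n_sims))
        records.append(
            {
                "N": N, "K": K, "L": L, "k": k_obs,
                "p_true": p_true, "p_emp": p_emp, "se": se,
                "within_3se": abs(p_emp - p_true) <= 3.0 * se,
            }
        )
    frac = sum(r["within_3se"] for r in records) / len(records)
    return {"configs": records, "agreement_fraction": frac, "n_sims": n_sims}


# ---------------------------------------------------------------------------
# weighted null vs exact enumeration

#: Small weighted instances: (target multiset, L, gene list).
ENUMERABLE_INSTANCES: tuple[tuple[tuple[str, ...], int, tuple[str, ...]], ...] = (
    (("A", "A", "A", "B"), 2, ("A",)),
    (("A", "A", "B", "C"), 2, ("B", "C")),
    (("A", "A", "B", "B", "C", "D", "E"), 3, ("A", "C")),
    (("A",) * 5 + ("B",) * 3 + ("C", "D", "E", "F"), 3, ("A", "B")),
    (("A", "A", "A", "B", "C", "C", "D", "E", "F", "F", "G", "H"), 4, ("A", "F", "H")),
    (tuple("ABCDEFGHIJKL"), 5, ("A", "B", "C")),
)


def weighted_null_check(seed: int, n_sims: int = 100_000) -> dict:
    """Total-variation distance between simulated and enumerated nulls."""
    records = []
    for i, (symbols, L, target_syms) in enumerate(ENUMERABLE_INSTANCES):
        bg = Background.from_symbols(symbols)
        target = GeneSet.from_symbols(target_syms, name=f"target{i}")
        exact = brute_force_null(bg, L, target)
        counts = simulate_match_counts(
            bg, L, target, n_sims, derive_seed(seed, "weighted", i)
        )
        ks, ns = np.unique(counts, return_counts=True)
        emp = {int(k): n / n_sims for k, n in zip(ks, ns)}
        support = set(exact) | set(emp)
        tv = 0.5 * sum(abs(emp.get(k, 0.0) - exact.get(k, 0.0)) for k in support)
        records.append(
            {"instance": i, "n_targets": len(symbols), "L": L, "tv": tv}
        )
    return {
        "instances": records,
        "max_tv": max(r["tv"] for r in records),
        "n_sims": n_sims,
    }


# ---------------------------------------------------------------------------
# type-I-error calibration

def calibration_experiment(
    seed: int,
    n_replicates: int = 200,
    n_genes: int = 2000,
    L: int = 400,
    set_size: int = 500,
    n_sims: int = 2000,
    alpha: float = 0.05,
) -> dict:
    """Rejection rate under the null of a random gene list of interest.

    The background is duplicate-free, so a uniformly random gene list makes
    the hypergeometric distribution the truth for the observed overlap and
    the test's simulated null matches it; deviations of the rejection rate
    from ``alpha`` then reflect Monte-Carlo noise and p-value discreteness
    only. The default dimensions give a large mean overlap (L*K/N = 100) so
    the discrete null support is fine near ``alpha``: the exact rejection
    probability of the ``p <= alpha`` rule under these defaults is 0.044
    (computable from the hypergeometric tail and binomial smoothing of the
    Monte-Carlo p-value); a discrete test rejecting at ``p <= alpha`` can
    only be conservative, never anti-conservative.
    """
    bg = _uniform_background(n_genes)
    top = bg.unique_genes[:L]
    genes = np.array(bg.unique_genes)
    rejections = 0
    p_values = []
    for rep in range(n_replicates):
        child = derive_seed(seed, "calibration", rep)
        rng = np.random.default_rng(child)
        target = GeneSet.from_symbols(
            rng.choice(genes, size=set_size, replace=False), name=f"null{rep}"
        )
        observed, _ = count_matches(top, target)
        counts = simulate_match_counts(
            bg, L, target, n_sims, derive_seed(seed, "calibration-sims", rep)
        )
        p = float(np.mean(counts >= observed))
        p_values.append(p)
        rejections += p <= alpha
    return {
        "rejection_rate": rejections / n_replicates,
        "alpha": alpha,
        "n_replicates": n_replicates,
        "p_values": p_values,
    }


# ---------------------------------------------------------------------------
# power vs planted overlap

#: The standard synthetic configuration for power experiments.
STANDARD_POWER_SPEC = dict(
    n_genes=500, target_set_size=50, n_top=50, probes_per_gene=1
)


def power_curve(
    seed: int,
    planted_levels: Sequence[int] = (0, 5, 10, 20),
    n_replicates: int = 9,
    n_sims: int = 10_000,
) -> dict:
    """Median enrichment p-value as a function of planted overlap."""
    medians = {}
    for level in planted_levels:
        ps = []
        for rep in range(n_replicates):
            child = derive_seed(seed, "power", level, rep)
            spec = SyntheticSpec(
                planted_overlap=level, seed=child, **STANDARD_POWER_SPEC
            )
            data = generate_dataset(spec)
            records = _parse_ranked(data.ranked_tsv)
            target = GeneSet.from_symbols(
                data.truth["target_genes"], name=f"planted{level}"
            )
            result = run_mset(
                records, target, n_top=spec.n_top, n_sims=n_sims,
                seed=derive_seed(seed, "power-sims", level, rep),
            )
            ps.append(result.p_value)
        medians[int(level)] = statistics.median(ps)
    return {
        "median_p": medians,
        "n_replicates": n_replicates,
        "n_sims": n_sims,
    }


def _parse_ranked(tsv_text: str):
    """Parse generated ranked-results text through the real file loader."""
    import tempfile
    from pathlib import Path

    with tempfile.TemporaryDirectory() as d:
        path = Path(d) / "ranked.tsv"
        path.write_text(tsv_text, encoding="utf-8")
        return load_ranked_results(path)


# ---------------------------------------------------------------------------
# specificity (2x2 crossed design)

def specificity_experiment(
    seed: int,
    n_sims: int = 10_000,
    alpha: float = 0.05,
    planted_overlap: int = 15,
) -> dict:
    """Each disease list should be significant only in its own dataset."""
    design = generate_specificity_design(
        seed=derive_seed(seed, "specificity-design"),
        planted_overlap=planted_overlap,
    )
    p = {}
    for db_name, symbols in design["gene_lists"].items():
        target = GeneSet.from_symbols(symbols, name=db_name)
        for ds_name, data in design["datasets"].items():
            records = _parse_ranked(data.ranked_tsv)
            result = run_mset(
                records, target, n_top=data.truth["n_top"], n_sims=n_sims,
                seed=derive_seed(seed, "specificity", db_name, ds_name),
                dataset_name=ds_name,
            )
            p[(db_name, ds_name)] = result.p_value
    diagonal = [("disease_A", "dataset_A"), ("disease_B", "dataset_B")]
    off_diagonal = [("disease_A", "dataset_B"), ("disease_B", "dataset_A")]
    return {
        "p_values": p,
        "alpha": alpha,
        "diagonal_significant": sum(p[c] <= alpha for c in diagonal),
        "off_diagonal_significant": sum(p[c] <= alpha for c in off_diagonal),
    }
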