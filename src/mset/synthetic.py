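"""Synthetic ranked-results generation with known, planted structure.

Every other module is testable without downloading any real platform data:
the generator emits a ranked results file (probe id + gene symbol TSV), a
gene list of interest, and a truth record describing exactly what was
planted — probe multiplicities, unannotated targets, and how many gene-list
members sit inside the top block of the ranking.

The generated structure mirrors what a significance-ranked microarray export
looks like to the test: annotated and unannotated targets, genes measured by
multiple probe sets, and a top region whose gene-list overlap is controlled.
It makes no attempt to model expression values, gene-gene correlation, or
realistic symbol vocabularies.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .genelist_io import GeneSet, SignificantGeneList


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one generated dataset.

    ``probes_per_gene`` is either a constant integer or a mapping
    ``{probe_count: probability}`` sampled independently per gene.
    ``planted_overlap`` gene-list members are forced into the top
    ``n_top``-unique-gene block (at uniformly random ranks within it); the
    remaining top slots are filled with genes outside the list, so the
    observed overlap equals the planted overlap by construction.
    ``exclude_from_top`` bars additional symbols from the top block, which
    is what a specificity design needs.
    """

    n_genes: int
    target_set_size: int
    n_top: int
    planted_overlap: int = 0
    probes_per_gene: int | Mapping[int, float] = 1
    n_unannotated: int = 0
    seed: int = 0
    exclude_from_top: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if min(self.n_genes, self.target_set_size, self.n_top) < 1:
            raise ValueError("n_genes, target_set_size and n_top must be >= 1")
        if self.planted_overlap < 0 or self.n_unannotated < 0:
            raise ValueError("counts must be >= 0")
        if self.planted_overlap > min(self.target_set_size, self.n_top):
            raise ValueError(
                "planted_overlap cannot exceed min(target_set_size, n_top)"
            )
        if max(self.target_set_size, self.n_top) > self.n_genes:
            raise ValueError("target set and top block must fit in n_genes")
        if isinstance(self.probes_per_gene, int):
            if self.probes_per_gene < 1:
                raise ValueError("probes_per_gene must be >= 1")
        else:
            probs = list(self.probes_per_gene.values())
            if not np.isclose(sum(probs), 1.0) or min(probs) < 0:
                raise ValueError("probes_per_gene probabilities must sum to 1")
            if min(self.probes_per_gene) < 1:
                raise ValueError("probe counts must be >= 1")


class SyntheticDataset(NamedTuple):
    """Generated file contents plus the ground-truth record."""

    ranked_tsv: str
    gene_list: str
    truth: dict


def _draw_multiplicities(
    spec: SyntheticSpec, genes: Sequence[str], rng: np.random.Generator
) -> dict[str, int]:
    if isinstance(spec.probes_per_gene, int):
        return {g: spec.probes_per_gene for g in genes}
    counts = np.array(sorted(spec.probes_per_gene), dtype=np.int64)
    probs = np.array([spec.probes_per_gene[int(c)] for c in counts])
    draws = rng.choice(counts, size=len(genes), p=probs / probs.sum())
    return {g: int(m) for g, m in zip(genes, draws)}


def generate_dataset(
    spec: SyntheticSpec,
    gene_universe: Sequence[str] | None = None,
    target_genes: Sequence[str] | None = None,
) -> SyntheticDataset:
    """Generate a ranked results file, gene list and truth record.

    Deterministic per ``spec.seed``. ``gene_universe`` and ``target_genes``
    may be supplied to share a platform and gene lists across datasets
    (needed for multi-dataset designs); by default both are created from the
    spec.
    """
    rng = np.random.default_rng(spec.seed)
    if gene_universe is None:
        genes = [f"G{i:05d}" for i in range(1, spec.n_genes + 1)]
    else:
        genes = [g.strip().upper() for g in gene_universe]
        if len(set(genes)) != len(genes) or len(genes) != spec.n_genes:
            raise ValueError("gene_universe must hold n_genes unique symbols")

    if target_genes is None:
        target = list(rng.choice(genes, size=spec.target_set_size, replace=False))
    else:
        target = [g.strip().upper() for g in target_genes]
        if not set(target) <= set(genes):
            raise ValueError("target_genes must be drawn from the universe")
        if len(target) != spec.target_set_size:
            raise ValueError("target_genes length must equal target_set_size")
    target_set = set(target)

    excluded = {s.strip().upper() for s in spec.exclude_from_top}
    filler_pool = [g for g in genes if g not in target_set and g not in excluded]
    n_filler = spec.n_top - spec.planted_overlap
    if n_filler > len(filler_pool):
        raise ValueError(
            f"cannot fill top block: need {n_filler} non-target genes, "
            f"only {len(filler_pool)} available"
        )

    planted = list(rng.choice(target, size=spec.planted_overlap, replace=False))
    filler = list(rng.choice(filler_pool, size=n_filler, replace=False))
    top_block = planted + filler
    rng.shuffle(top_block)  # planted genes land at uniform ranks in the block

    rest = [g for g in genes if g not in set(top_block)]
    rng.shuffle(rest)
    gene_order = top_block + rest

    multiplicity = _draw_multiplicities(spec, genes, rng)

    # one row per gene in ranking order, then scatter duplicate probes below
    # each gene's first occurrence so the unique-gene order is preserved
    rows: list[str | None] = list(gene_order)
    extras = [g for g in gene_order for _ in range(multiplicity[g] - 1)]
    for g in extras:
        first = rows.index(g)
        pos = int(rng.integers(first + 1, len(rows) + 1))
        rows.insert(pos, g)
    for _ in range(spec.n_unannotated):
        pos = int(rng.integers(0, len(rows) + 1))
        rows.insert(pos, None)

    lines = ["probe_id\tgene_symbol"]
    lines += [
        f"P{i + 1:06d}\t{'' if g is None else g}" for i, g in enumerate(rows)
    ]
    ranked_tsv = "\n".join(lines) + "\n"
    gene_list = "\n".join(sorted(target)) + "\n"

    truth = {
        "n_genes": spec.n_genes,
        "n_targets_annotated": len(rows) - spec.n_unannotated,
        "n_unannotated": spec.n_unannotated,
        "target_genes": sorted(target),
        "planted_genes": sorted(planted),
        "planted_overlap": spec.planted_overlap,
        "n_top": spec.n_top,
        "top_block_genes": list(top_block),
        "probe_multiplicity": dict(sorted(multiplicity.items())),
        "seed": spec.seed,
    }
    return SyntheticDataset(ranked_tsv=ranked_tsv, gene_list=gene_list, truth=truth)


def generate_specificity_design(
    n_genes: int = 500,
    set_size: int = 50,
    planted_overlap: int = 15,
    n_top: int = 50,
    seed: int = 0,
) -> dict:
    """A 2x2 cross design: each disease list planted only in its own dataset.

    Two disjoint gene lists (A, B) share one platform; dataset A's top block
    holds ``planted_overlap`` A-genes and no B-genes, and vice versa. Under
    the test, only the matching (list, dataset) cells should be significant.
    """
    rng = np.random.default_rng(seed)
    genes = [f"G{i:05d}" for i in range(1, n_genes + 1)]
    picks = rng.choice(genes, size=2 * set_size, replace=False)
    list_a, list_b = list(picks[:set_size]), list(picks[set_size:])
    seeds = np.random.SeedSequence(seed).generate_state(2)

    def _make(target, other, child_seed):
        spec = SyntheticSpec(
            n_genes=n_genes,
            target_set_size=set_size,
            n_top=n_top,
            planted_overlap=planted_overlap,
            seed=int(child_seed) % (2**31),
            exclude_from_top=tuple(other),
        )
        return generate_dataset(spec, gene_universe=genes, target_genes=target)

    return {
        "gene_lists": {"disease_A": sorted(list_a), "disease_B": sorted(list_b)},
        "datasets": {
            "dataset_A": _make(list_a, list_b, seeds[0]),
            "dataset_B": _make(list_b, list_a, seeds[1]),
        },
    }


def consensus_filter(
    tables: Sequence[GeneSet],
    results: SignificantGeneList | Sequence[str],
    min_databases: int = 3,
) -> list[tuple[str, int]]:
    """Genes of the significant results backed by several databases.

    Counts, for every gene in ``results``, the number of gene sets that
    contain it, and returns the genes reaching ``min_databases``, sorted by
    count descending then symbol.
    """
    if min_databases < 1:
        raise ValueError("min_databases must be >= 1")
    counts = Counter()
    for sym in results:
        counts[sym] = sum(1 for t in tables if sym in t.symbols)
    kept = [(s, c) for s, c in counts.items() if c >= min_databases]
    return sorted(kept, key=lambda sc: (-sc[1], sc[0]))


def load_table1_fixture() -> pd.DataFrame:
    """The packaged consensus-gene table (symbol, n_databases, gene_name).

    Symbols are returned as printed; normalize with
    :func:`mset.normalize_symbol` before matching.
    """
    path = resources.files("mset.data") / "table1_autism_consensus.tsv"
    with resources.as_file(path) as p:
        df = pd.read_csv(p, sep="\t", comment="#")
    if df["symbol"].duplicated().any():
        raise ValueError("fixture contains duplicate symbols")
    if (df["n_databases"] < 3).any():
        raise ValueError("fixture violates its >= 3 databases inclusion rule")
    return df
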