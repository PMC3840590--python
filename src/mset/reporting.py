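"""Output surfaces: text readout, null-distribution plot, enrichment heat map.

A single run yields two primary outputs: a text readout summarising the
inputs, the simulated null and the enrichment p-value (with the matched
gene roster), and a plot of the null match-count distribution with an arrow
at the observed value. Batches of runs over several gene lists and datasets
assemble into a p-value matrix rendered as a discrete-binned heat map.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")  # file output only; no display server assumed

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib.colors import BoundaryNorm, ListedColormap

from .core import EnrichmentResult

#: Default half-open significance bins for heat-map colouring.
DEFAULT_BIN_EDGES: tuple[float, ...] = (0.001, 0.01, 0.05)

_BIN_COLORS = ("#08306b", "#2171b5", "#6baed6", "#f0f0f0")
_ABSENT_COLOR = "#bdbdbd"


def bin_label(p: float, bin_edges: Sequence[float] = DEFAULT_BIN_EDGES) -> str:
    """Half-open significance bin for a p-value (p < edge)."""
    for edge in sorted(bin_edges):
        if p < edge:
            return f"p<{edge:g}"
    return f"p>={max(bin_edges):g}"


def render_text_report(result: EnrichmentResult) -> str:
    """Human-readable readout of one enrichment run."""
    lines = [
        "MSET enrichment analysis",
        "========================",
        f"gene list of interest : {result.database_name} "
        f"({result.gene_set_size} genes)",
        f"expression dataset    : {result.dataset_name}",
        f"background            : {result.background_n_targets} annotated targets, "
        f"{result.background_n_unique_genes} unique genes",
        f"significant list      : L={result.L} unique genes "
        f"(n_top={result.n_top}, mode={result.threshold_mode})",
        f"simulated results     : {result.n_sims} (seed={result.seed})",
        "",
        f"observed matches to database : {result.observed_matches}",
        f"enrichment p-value           : {result.p_value_display()}",
        "",
        f"matched genes ({result.observed_matches}):",
    ]
    if result.matched_genes:
        lines += [f"  {g}" for g in result.matched_genes]
    else:
        lines += ["  (none)"]
    return "\n".join(lines) + "\n"


def distribution_figure(result: EnrichmentResult):
    """Matplotlib figure of the null match-count distribution.

    Bar heights are probabilities (counts / n_sims); an arrow marks the
    observed match count and the p-value is annotated.
    """
    pmf = result.null.pmf()
    ks = np.arange(0, max(result.null.max_matches, result.observed_matches) + 2)
    heights = np.array([pmf.get(int(k), 0.0) for k in ks])

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(ks, heights, width=0.9, color="#74a9cf", edgecolor="white")
    top = heights.max() if heights.max() > 0 else 1.0
    ax.annotate(
        f"observed = {result.observed_matches}",
        xy=(result.observed_matches, 0.0),
        xytext=(result.observed_matches, top * 0.55),
        arrowprops=dict(arrowstyle="-|>", color="#08306b", lw=2),
        color="#08306b",
        ha="center",
    )
    ax.set_xlabel("matches to database in simulated results")
    ax.set_ylabel("probability")
    ax.set_title(
        f"{result.database_name} in {result.dataset_name}\n"
        f"p = {result.p_value_display()}  "
        f"(L={result.L}, {result.n_sims} simulated results)"
    )
    fig.tight_layout()
    return fig, ax


def render_distribution_plot(result: EnrichmentResult, path: str | Path) -> Path:
    """Write the null-distribution plot; format follows the file extension."""
    path = Path(path)
    fig, _ = distribution_figure(result)
    fig.savefig(path)
    plt.close(fig)
    return path


@dataclass(frozen=True)
class EnrichmentMatrix:
    """p-values of many runs arranged databases x datasets.

    Missing (database, dataset) combinations are NaN ("absent").
    """

    p_values: pd.DataFrame
    bin_edges: tuple[float, ...] = DEFAULT_BIN_EDGES

    def __post_init__(self) -> None:
        if self.p_values.empty:
            raise ValueError("enrichment matrix has no rows or columns")
        vals = self.p_values.to_numpy(dtype=float)
        present = vals[~np.isnan(vals)]
        if present.size and ((present < 0) | (present > 1)).any():
            raise ValueError("p-values outside [0, 1]")

    def binned(self) -> pd.DataFrame:
        """String bin labels per cell; empty string where absent."""
        return self.p_values.map(
            lambda p: "" if pd.isna(p) else bin_label(p, self.bin_edges)
        )

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        self.p_values.to_csv(path, sep="\t", index_label="database", na_rep="NA")
        return path


def build_matrix(
    results: Sequence[EnrichmentResult],
    bin_edges: Sequence[float] = DEFAULT_BIN_EDGES,
) -> EnrichmentMatrix:
    """Assemble run results into a databases x datasets p-value matrix."""
    if not results:
        raise ValueError("no results to assemble")
    seen = set()
    for r in results:
        key = (r.database_name, r.dataset_name)
        if key in seen:
            raise ValueError(f"duplicate (database, dataset) pair {key}")
        seen.add(key)
    rows = list(dict.fromkeys(r.database_name for r in results))
    cols = list(dict.fromkeys(r.dataset_name for r in results))
    mat = pd.DataFrame(np.nan, index=rows, columns=cols)
    for r in results:
        mat.loc[r.database_name, r.dataset_name] = r.p_value
    return EnrichmentMatrix(p_values=mat, bin_edges=tuple(sorted(bin_edges)))


def render_heatmap(matrix: EnrichmentMatrix, path: str | Path) -> Path:
    """Discrete-binned heat map of the enrichment matrix."""
    path = Path(path)
    edges = list(matrix.bin_edges)
    boundaries = [0.0] + edges + [1.0 + 1e-9]
    cmap = ListedColormap(_BIN_COLORS[: len(boundaries) - 1])
    cmap.set_bad(_ABSENT_COLOR)
    norm = BoundaryNorm(boundaries, cmap.N)

    vals = np.ma.masked_invalid(matrix.p_values.to_numpy(dtype=float))
    n_rows, n_cols = vals.shape
    fig, ax = plt.subplots(
        figsize=(2 + 1.2 * n_cols, 1.5 + 0.45 * n_rows)
    )
    im = ax.imshow(vals, cmap=cmap, norm=norm, aspect="auto")
    ax.set_xticks(range(n_cols), labels=matrix.p_values.columns, rotation=30,
                  ha="right")
    ax.set_yticks(range(n_rows), labels=matrix.p_values.index)
    cbar = fig.colorbar(im, ax=ax, ticks=boundaries)
    cbar.set_label("enrichment p-value")
    ax.set_title("enrichment summary")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return path


def render_redundancy_heatmap(matrix: pd.DataFrame, path: str | Path) -> Path:
    """Continuous heat map of pairwise gene-list redundancy (0..1)."""
    path = Path(path)
    n = len(matrix)
    fig, ax = plt.subplots(figsize=(2 + 0.6 * n, 2 + 0.6 * n))
    im = ax.imshow(matrix.to_numpy(), cmap="RdYlGn", vmin=0.0, vmax=1.0)
    ax.set_xticks(range(n), labels=matrix.columns, rotation=45, ha="right")
    ax.set_yticks(range(n), labels=matrix.index)
    fig.colorbar(im, ax=ax, label="redundancy (shared / smaller list)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return path


def write_run_outputs(
    result: EnrichmentResult, outdir: str | Path, plot_format: str = "png"
) -> dict[str, Path]:
    """Write the standard per-run artifact set into ``outdir``.

    result.json, null_histogram.tsv, matched_genes.tsv, report.txt and
    distribution.<fmt>; returns the written paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    paths["json"] = outdir / "result.json"
    paths["json"].write_text(result.to_json() + "\n", encoding="utf-8")

    hist = pd.DataFrame(
        sorted(result.null.counts.items()), columns=["matches", "count"]
    )
    hist["probability"] = hist["count"] / result.n_sims
    paths["histogram"] = outdir / "null_histogram.tsv"
    hist.to_csv(paths["histogram"], sep="\t", index=False)

    paths["matched"] = outdir / "matched_genes.tsv"
    pd.DataFrame({"gene": list(result.matched_genes)}).to_csv(
        paths["matched"], sep="\t", index=False
    )

    paths["report"] = outdir / "report.txt"
    paths["report"].write_text(render_text_report(result), encoding="utf-8")

    paths["plot"] = render_distribution_plot(
        result, outdir / f"distribution.{plot_format}"
    )
    return paths
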