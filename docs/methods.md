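# Methods

## Model and procedure

The test treats a ranked expression experiment as a draw of *L* unique genes
from a finite platform and asks whether the observed draw is unusually rich
in members of a fixed gene list of interest *D*. The null hypothesis is that
the top of the ranking is exchangeable with any other platform-weighted
selection of *L* unique genes.

Sampling is performed at the level of platform targets (probe sets), not
genes. The background retains every annotated target, so a gene covered by
*m* probe sets has *m* chances per draw. One simulated result is obtained by
drawing `2L` targets without replacement, collapsing duplicate genes (first
occurrence kept), truncating to the first *L* unique genes, and — in the
rare case fewer than *L* distinct genes were drawn — continuing with single
without-replacement draws until *L* are held. This composite procedure is
*exactly* the first *L* unique genes along a uniform random permutation of
the background targets; the vectorised sampler implements that equivalence
(random keys, `argpartition` of the `2L` smallest, within-prefix ordering,
first-occurrence deduplication) and falls back to walking the full
permutation for the rows that need topping up. For duplicate-free
backgrounds only the unordered *L*-subset matters and the ordering step is
skipped; either way the draw is exact, not approximate.

The empirical p-value is the plain proportion of simulated results with at
least as many matches as observed, with no +1 smoothing — the published
definition of the randomization test. A p of exactly 0 is stored as 0.0 and
displayed as `< 1/n_sims`, making the Monte-Carlo resolution floor explicit.

The truncation rule deserves a note: for weighted backgrounds, "the first
*L* unique genes in draw order" is *not* distributionally the same as a
uniform *L*-subset of the unique genes in the `2L` draw — high-multiplicity
genes tend to occur earlier in the permutation, so order-respecting
truncation preserves the platform weighting consistently. The brute-force
enumerator uses the same draw-order semantics, so the cross-validation
between engine and oracle is over the identical process.

### Assumptions

* Gene-level independence: the null permutes genes freely and models no
  gene–gene correlation; disease gene lists are heterogeneous,
  phenotype-curated collections, for which this is a reasonable assumption
  (functional pathway lists are better served by sample-permuting methods).
* The input ranking is taken as given (file order); how significance was
  computed upstream is out of scope.
* Symbols match exactly after normalization (strip + uppercase). No alias,
  ortholog, or cross-species mapping is attempted: a list curated in another
  symbol vocabulary will silently fail to match, which is the user's
  responsibility to resolve upstream.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `n_top` | required | how many top genes form the significant list; with `mode=unique_genes` (default) the scan continues past duplicates/unannotated rows until `n_top` *unique* genes are held, so `L = n_top`; `mode=raw_rows` takes `n_top` physical rows and filters, so `L ≤ n_top` |
| `n_sims` | 10,000 | simulated results; p-value resolution is `1/n_sims`. Hard minimum 100, warning below 1,000 |
| `seed` | 0 | root seed; every simulated result derives from it deterministically |
| `na_sentinels` | `---`, `NA`, `N/A`, `NULL` | symbol-field values treated as "unannotated" besides blank |
| heat-map bins | 0.001, 0.01, 0.05 | half-open significance bins (`p < edge`); conventional thresholds, configurable per batch manifest |

The `unique_genes` default keeps *L* identical across datasets analysed with
the same `n_top`, which is what makes a multi-dataset heat map comparable
column to column.

## Randomness and determinism

All randomness flows from one integer seed. The engine simulates in fixed
chunks of 4,096 results; chunk *i*'s generator is spawned from
`SeedSequence(seed)`, so a run is bit-reproducible and does not depend on
how many simulations are requested. Batch grids derive one child seed per
(gene list, dataset) cell by hashing the labels into a `SeedSequence`, so
adding a cell never perturbs existing ones. Replicated experiments derive
per-replicate seeds the same way.

## Synthetic data

The generator emulates the *structure* the test consumes: a
significance-ordered TSV of targets with configurable probes-per-gene
multiplicity (constant or categorical), a configurable count of unannotated
rows interleaved at random positions, and a top block of `n_top` unique
genes containing an exact, planted number of gene-list members at uniform
random ranks within the block (remaining top slots are filled from
non-list genes, so observed overlap equals the planted overlap by
construction). Duplicate probes are scattered at random positions below
their gene's first occurrence, which preserves the unique-gene order.

It does **not** emulate expression values, realistic significance gradients,
gene–gene correlation, annotation vocabularies, or any particular chip.
Passing tests on synthetic data therefore demonstrate the correctness of the
algorithmic pipeline and its statistical calibration under independence —
not robustness to correlated genes or noisy annotation, which no
randomization at the gene level can establish.

A packaged consensus table (`mset/data/table1_autism_consensus.tsv`) lists
36 autism-associated genes found among significant postpartum
lateral-septum expression changes together with the number of independent
autism databases (of nine) containing each; it backs the consensus-filter
checks without redistributing the source databases themselves.

## Validation experiments

* **Hypergeometric agreement** — 20 duplicate-free configurations with
  `N ∈ [50, 5000]` (log-spaced), `K/N ∈ [0.01, 0.5]`, `L ∈ [5, 500]`,
  100,000 simulations each; the empirical tail probability must sit within
  three binomial standard errors of the exact tail. The observed count is
  set at the null mean, where the standard error is informative.
* **Weighted-null exactness** — six multi-probe backgrounds of ≤ 12 targets
  are enumerated exactly (dynamic programming over exchangeable gene
  classes, rational arithmetic) and compared with 100,000 simulations by
  total-variation distance (bound 0.02).
* **Type-I calibration** — 200 replicates draw a random 500-gene list
  against a fixed duplicate-free 2,000-gene background (L = 400,
  2,000 simulations each); the rejection rate at α = 0.05 must lie in
  [0.02, 0.10]. The dimensions were chosen so the exact level of the
  discrete `p ≤ α` rule, computable in closed form, is 0.044 — as close to
  α as such a rule can get; it is conservative by construction.
* **Power** — median p over 9 replicates strictly decreases as the planted
  overlap grows through 0, 5, 10, 20 on the standard design (500 genes,
  50-gene list, `n_top = 50`).
* **Specificity** — a 2×2 design plants each of two disjoint lists only in
  its own dataset (the other list's genes are barred from the top block);
  only the two matching cells may be significant at α = 0.05.
* **Determinism** — repeating a CLI invocation with the same seed must
  reproduce `result.json` byte for byte.

Problem sizes throughout are chosen so the full suite and the acceptance
script each complete in minutes on a single core while keeping every
statistical bound at least three standard errors wide.

## Numerical and degenerate-input choices

* `hypergeom_tail` delegates to `scipy.stats.hypergeom.sf` (log-gamma
  based); tests cross-check it against exact rational enumeration.
* Empty gene sets, all-unannotated rankings, `n_top` exceeding the unique
  genes available, `L` exceeding the background's gene complement, and
  duplicate set names all raise `ValueError` with the offending quantity.
* When `2L` exceeds the background size the sampler degrades gracefully to
  sequential drawing (logged), which is the same permutation-walk process.
* Ties in the upstream ranking are invisible to the test: order is file
  order.

## Known limitations

* Matching is exact-string after normalization; species or alias mismatches
  silently reduce observed and simulated matches alike (the test stays
  internally consistent but loses power).
* No multiple-testing correction is applied across gene lists or datasets;
  the heat map reports raw per-cell p-values and is meant as a
  meta-analytic overview, not a corrected inference.
* Very small gene lists produce spiky, highly discrete nulls; a single
  chance match then moves the p-value by a large step. The resolution floor
  `1/n_sims` is reported, but interpretation of near-threshold p-values on
  small lists warrants caution.
* The weighted-null enumerator is exponential in background size and is a
  validation device only (≤ 15 targets).
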