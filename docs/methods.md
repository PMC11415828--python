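# Methods

## Model

`scintruler` treats each data source $S_k$ ($k = 1, \dots, K$, $K \ge 2$)
as a gene-by-cell matrix over a common gene index $g = 1, \dots, G$ (the
intersection of the sources' gene sets, matched by exact identifier). The
question it answers is whether cells are systematically closer to cells of
their own source than to cells of other sources, evaluated at the level of
small, randomly formed cell groups.

**Fine clusters as sampling units.** Within each source, broad clusters are
found by Louvain modularity optimization on a shared-nearest-neighbor
graph: 20-NN search in a 50-dimensional PCA embedding of the 2000 most
dispersed genes (log-normalized to 10,000 counts per cell, per-gene
standardized), edges weighted by the Jaccard similarity of neighbor sets
and pruned below 1/15, resolution 0.5. Each broad cluster is then split
uniformly at random into fine clusters (3 parts if > 200 cells, 2 parts if
50–200, else kept whole; equal-probability multinomial assignment,
resampled until every part is nonempty). Because the split is random, fine
clusters are evenly distributed within their broad cluster: any systematic
within-vs-between difference they exhibit reflects the source structure,
not the split.

**Distances.** All distances use cosine-normalized expression — each cell's
log-normalized profile scaled to unit Euclidean norm — over all shared
genes (optionally restricted to the HVG union). Unit norms make Euclidean
distance depth-free and bound any pairwise distance by 2. For each fine
cluster: 20 query cells are sampled from it; a within pool of 500 cells
from the same-source complement of the fine cluster; a between pool of 500
cells from each other source (stratified, $500 \cdot (K-1)$ total). All
draws are without replacement and capped at availability. Each query cell
contributes its 15 smallest distances in each pool, giving arrays
$d_\text{within}$ and $d_\text{between}$ of $20 \times 15 = 300$ elements.
If a pool is smaller than 15, k is reduced for *both* arrays so they stay
comparable.

**Test and score.** $T = \bar d_\text{between} - \bar d_\text{within}$ is
tested against $H_0\!: \mu_\text{between} \le \mu_\text{within}$ by Monte
Carlo label permutation of the pooled 600 values (1000 permutations). The
p-value uses the add-one convention $p = (1 + \#\{T^\ast \ge T_\text{obs}\})
/ (1 + N)$ so it is never exactly 0; `raw_pvalue=True` restores the plain
$\#\{T^\ast \ge T_\text{obs}\}/N$ estimator (the two differ by at most
$1/N$). Each cluster's RWBD is
$(\bar d_\text{between} - \bar d_\text{within}) / \max(\bar d_\text{between},
\bar d_\text{within})$, computed from the 300-element k-NN arrays. The
SCIntRuler score is the fraction of fine clusters with $p < 0.1$ (strict)
and RWBD $> 0$; clusters whose test cannot be computed (e.g. a fine cluster
covering its entire source) are reported separately and excluded from the
denominator. Cells of clusters with $p > 0.9$ and RWBD $< 0$ are flagged as
shared populations.

A deliberate asymmetry is worth noting: with $K \ge 3$ the between pool
($500 \cdot (K-1)$ cells) is larger than the within pool (500), so under
exchangeability the between k-NN distances are stochastically *smaller*
(minima over more candidates) and the test is conservative — fully shared
sources yield p-values near 1, not uniform, and a score of 0. With equal
pool sizes ($K = 2$) the null p-value is approximately uniform and
individual null clusters can pass at rate $\lesssim$ 0.1.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `resolution` | 0.5 | Louvain resolution; the one clustering setting the method fixes |
| `knn_k` | 20 | neighbors for the SNN graph |
| `n_hvg`, `n_pcs` | 2000, 50 | clustering front-end (HVGs by variance/mean dispersion, deterministic gene-id tie-break; PCA sign fixed by making each component's largest loading positive) |
| `fine_thresholds` | (50, 200) | fine-split boundaries, inclusive: 50–200 cells → 2 parts, > 200 → 3 |
| `n_query`, `n_within`, `n_between_per_source`, `k_nn` | 20, 500, 500, 15 | sampling scheme; arrays have length `n_query * k_nn` |
| `n_perm` | 1000 | Monte-Carlo permutations; p granularity 1/(N+1) |
| `p_cut`, `shared_p` | 0.1, 0.9 | strict thresholds for the score numerator and the shared flag |
| `bands` | (0.2, 0.8) | recommendation boundaries: [0, .2) any method, [.2, .8] balanced methods, (.8, 1] simple merge |
| `distance_genes` | `all` | distances over all shared genes; `hvg` restricts to the per-source HVG union |
| `within_pool` | `source` | within pool = same-source complement of the fine cluster; `broad` restricts to the broad cluster |

One integer seed drives everything: per-source clustering, fine splits,
pool sampling and permutations receive independent child seeds via a seed
sequence, so a fitted result is exactly reproducible. igraph's Louvain
draws from Python's stdlib RNG; it is seeded locally and the prior state
restored.

## Synthetic data generator

`synthetic.generate` draws counts
$X_{gc} \sim \mathrm{NB}(\mu_{gc}, \phi)$ with
$\mu_{gc} = \beta_g \cdot 2^{\lambda M_{t(c), g}} \cdot b_{k(c), g}$ and
$\mathrm{Var} = \mu + \phi \mu^2$: a gamma-distributed per-gene baseline
$\beta_g$ (mean `base_mean` = 0.5), disjoint 100-gene marker blocks per
cell type at log2 fold change $\lambda$ = 1.5, a per-source log-normal
batch factor $b$ (log-SD `batch_effect_sd`, default 0), and dispersion
$\phi$ = 0.5. Defaults give 1500 cells and 2000 genes per source so a full
run completes in seconds.

The presets control the presence structure, ordered by increasing sharing:
`disjoint` (one private type per source), `low_overlap` (one shared type,
300 cells, plus two private types of 600), `high_overlap` (shared type
dominant at 1350 cells, one 150-cell private type), `fully_shared`
(identical three-type composition everywhere). Presets default to
`batch_effect_sd = 0`, emulating designs where the sources are splits of a
single experiment, so cross-source separation in the presets is purely
biological; the parameter is exposed for studies of genuine platform
effects.

**What the generator does not emulate.** Counts are conditionally
independent across genes given type and source — no gene–gene correlation
modules, doublets, ambient RNA, library-size heterogeneity beyond NB
noise, or continuous (trajectory-like) populations. Marker effects
(100 genes at ~2.8-fold) are modest relative to count noise, so cosine
distances concentrate: between-type and within-type k-NN distances differ
by ~1% rather than the large relative gaps real cell types show. Two
consequences: observed |RWBD| values on synthetic data are small (~0.03)
even when separation is highly significant, and minority private types in
`high_overlap` (150 cells against a 1350-cell shared background) are
swamped in the k-NN comparison, pushing that preset's score toward 0
rather than an intermediate value. The score ordering across presets
(≈ 1, ≈ 0.67, ≈ 0, 0) remains strictly the sharing ordering; passing tests
demonstrate the metric's decision behavior under controlled sharing, not
its numerical output on any real tissue.

## Numerical and design choices

- The distance is the true Euclidean norm (square root applied). k-NN
  selection is invariant to the monotone square root, and RWBD is a ratio,
  so this choice affects scale only.
- k-NN ties at the boundary resolve by pool index order (deterministic);
  array *values* are unaffected by pool order.
- PCA uses the randomized solver with a fixed internal state; determinism
  across runs is guaranteed, and component signs are canonicalized.
- `rwbd(0, 0)` (identical degenerate data) returns 0 with a warning rather
  than raising, so a pathological cluster does not abort a study.
- Zero-total cells are dropped at ingest with a logged warning; cosine
  normalization is undefined for them.
- Gene matching across sources is by exact identifier; symbol/Ensembl
  mapping is deliberately out of scope (silent mismatches are worse than a
  small intersection).

## Problem sizes

Default analyses (3 × 1500 cells, 2000 genes) fit in seconds per run. The
bound checks in the test suite and `scripts/acceptance.py` use 100
randomized runs at reduced scale — ~300 cells per source, 500 genes,
pools of 150, 10-NN, 200 permutations — which exercises every pipeline
stage while keeping the full randomized sweep to a couple of minutes.
Replicate studies (`repeat_study`) report mean and SD of the score over
independently generated datasets; the monotonicity check uses 10
replicates per preset at full preset size.

## Limitations

- The recommendation bands are heuristics over the score; scores near a
  boundary deserve inspection of the per-cluster table rather than blind
  trust in the label.
- With exactly two sources the conservative pool-size asymmetry vanishes;
  expect a null score around 0.1 rather than 0.
- The permutation null is plain Monte Carlo; no asymptotic approximation
  is used, so very small p-values are floored at 1/(N+1).
- Louvain at resolution 0 collapses to one community only on a connected
  SNN graph; disconnected components never merge (no modularity gain).
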