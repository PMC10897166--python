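# Methods

## The reliability score

Given a genes × cells expression matrix (already normalized and
log-transformed to the user's taste — no normalization happens here) and a
2D embedding method, each cell receives a **reliability score** measuring
whether its ordered mid-range neighborhood survived the embedding.

With n cells and similarity percent x (default 50, the method's only
hyperparameter), the neighborhood size is m = round(x/100 · n), rounded
half-up and clamped to [2, n−1]. For cell i:

1. A = the m nearest cells in the **pre-embedding** space (top-K PCs or a
   user-supplied coordinate matrix), ordered closest to farthest;
2. B = the m nearest cells in the **2D-embedding** space, same ordering;
3. v_pre = cell i's 2D-embedding distances to the cells of A, in A's order;
4. v_emb = cell i's 2D-embedding distances to the cells of B, in B's order
   (non-decreasing by construction);
5. r_i = Pearson(v_pre, v_emb) ∈ [−1, 1].

Both distance vectors live in the 2D space; only the neighbor *order*
differs between spaces. This is deliberate: the actual embedded distances
carry the visual information a reader takes from the plot, so Pearson
correlation on distances (not Spearman on ranks) is used. If either vector
is constant — perfectly equidistant neighbors — the correlation is
undefined; such cells are labeled `undefined`, reported, and excluded from
dubious/trustworthy counts rather than silently scored 0.

Distances are Euclidean throughout; ties are broken by ascending cell index
so results are machine-independent. Scores are invariant to rigid motions
(rotation, translation, reflection) of either space and to the ordering of
genes in the matrix, but **not** to anisotropic rescaling of the 2D
coordinates, which genuinely changes what the plot shows.

## The permutation null and classification

A null distribution is obtained by shuffling each gene's values
independently across cells (one seeded permutation per run, default seed
100). This preserves every gene's marginal distribution while destroying
all cell–cell structure; on clustered synthetic data the silhouette of the
true labels collapses to ≈ 0 after permutation. The permuted matrix is
pushed through the *same* pipeline — PCA refit from scratch (the null never
reuses the original loadings), embedding with the same hyperparameter
setting and seed — and scored identically, yielding n null scores.

A cell is **dubious** iff its score ≤ the 5th percentile of the null scores
and **trustworthy** iff ≥ the 95th percentile (both percentiles
configurable; linear interpolation between order statistics, the default
quantile rule in the major numeric ecosystems; nearest-rank differences
vanish at realistic n). Undefined null scores are dropped, with a logged
count, before percentiles are taken. The fraction of cells flagged is
data-dependent: on well-structured data far more than 5% of cells are
trustworthy and far fewer than 5% dubious.

## Hyperparameter optimization

Functionality two: sweep a grid of embedder settings and choose the one
minimizing the number of dubious embeddings. Default candidate values:

* t-SNE perplexity: 20, 50, 80, …, 380, then 410, then 450, 500, …, 750,
  then 800 — filtered to perplexity < (n−1)/3, the standard embeddability
  constraint;
* UMAP n_neighbors: 5, 6, …, 30, 35, 40, 45, 50 (30 values, filtered to
  < n); min_dist: 0.0125, 0.05, 0.1, 0.2, …, 0.8 (10 values).

UMAP's two hyperparameters may be swept **jointly** (Cartesian product) or
**marginally** (one varies while the other is anchored; anchors default to
the user's original setting, falling back to the umap-learn defaults 15 and
0.1). The matrix is permuted once per run — the permutation precedes and is
independent of the embedder setting — and the permuted data is re-embedded
under each candidate setting.

Ties at the minimum go to the smallest hyperparameter value, with all
minimizers reported and logged. This is our choice (the tie rule is
otherwise unspecified) and intentionally avoids any drift toward large
neighborhood sizes, where dubious counts typically plateau.

As an alternative selector, the **kneedle** elbow rule is implemented for
one-dimensional sweeps: min–max normalize both axes, take the difference
between the (decreasing) normalized curve and its chord, and return the
hyperparameter value maximizing that difference. With sensitivity S = 1 a
knee is declared only when the maximum difference exceeds S times the mean
normalized spacing, so flat or linear count curves return no elbow.

## Embedders

t-SNE is delegated to scikit-learn (`TSNE`, PCA initialization, automatic
learning rate, single-threaded) and UMAP to umap-learn; fixing
`random_state` (default 100) pins both to their deterministic paths, giving
the bit-reproducibility the scoring contract assumes. A `passthrough`
embedder returning the first two pre-embedding dimensions exists for
testing: on a 2D pre-embedding it makes every reliability score exactly 1.
Coordinates are consumed exactly as the embedder produced them.

## Evaluation metrics

* **KNN** (local preservation): mean over cells of the fraction of the
  K = 10 nearest pre-embedding neighbors retained among the K = 10 nearest
  2D neighbors.
* **KNC** (global preservation): the same overlap over the K = 4 nearest
  *cluster centers*, where each center is the per-dimension **median** of
  its member cells (robust to outliers), computed separately in each space.
  The proportion is averaged per cell, and a cell's own cluster counts
  among the candidates by default (an `exclude_own` flag is provided).
* **Jaccard index** between dubious sets quantifies the stability of
  detection across similarity percents; it is defined as 1 when both sets
  are empty.

## Synthetic study designs

The generator produces k cell types whose gene-space mean vectors sit at
the vertices of a regular simplex on top of a shared gamma-distributed
baseline, with the simplex edge length equal to `separation` times the
within-cluster standard deviation. Noise is Gaussian by default — the
statistic consumes only distances, and Gaussian noise keeps `separation`
directly interpretable — with a log1p negative-binomial option for
count-like values. Cluster sizes follow the requested proportions by
largest-remainder apportionment, and everything is reproducible from one
seed. What the generator does **not** emulate: gene–gene correlation,
library-size variation, dropout, and mean–variance coupling of real
scRNA-seq counts. Passing tests therefore demonstrate the statistic's
behavior on cleanly clustered geometry, not robustness to every artifact
of real data.

Three designs recur in the tests and in `scripts/acceptance.py`; problem
sizes were fixed once as desk-scale versions of a realistic analysis:

* **Clean fixture** — n = 600 cells, 1000 genes, k = 3 clusters,
  separation 8: cleanly separable (silhouette > 0.5 in the K = 3 PC
  space). The optimizer reaches zero dubious embeddings here for both
  t-SNE (full feasible default grid, perplexity 20–170) and UMAP (marginal
  sweep over n_neighbors {5, 10, 15, 20, 30, 50} and min_dist {0.0125,
  0.1, 0.3, 0.5, 0.8} with anchors 15/0.1 — a reduced sweep chosen to keep
  the study minutes-scale on one CPU).
* **Small clean fixture** — n = 300, same geometry, swept down to
  perplexity 2 where distortions appear, giving the kneedle selector a
  real elbow (counts drop steeply then plateau at ~0).
* **Hard fixture** — n = 600, k = 8 clusters, separation 3: genuinely
  ambiguous geometry on which dubious embeddings occur (a few percent of
  cells at x = 50), used for the sensitivity analysis of the similarity
  percent. Dubious sets detected at x = 40, 50, 60 agree pairwise
  (Jaccard > 0.5) while x = 5 finds a largely different set — too small a
  neighborhood cannot see clusters whose *relative position* is dubious.

Throughout these studies the pre-embedding uses K = 5 PCs (the simplex
structure spans k−1 dimensions; 5 is a typical elbow-plot choice at this
scale), and the embedding/permutation seed is the method's convention of
100.

## Numerical and degenerate-input choices

* Pearson correlation is computed from centered dot products and clipped
  to [−1, 1]; a vector is declared constant by exact equality of all
  entries.
* PCA is a full SVD of the (centered, optionally scaled) cells × genes
  matrix; component signs are fixed by making each component's
  largest-magnitude loading positive, so repeated runs are bit-identical.
  Zero-variance genes are dropped with a warning when scaling. By default
  genes are centered but not scaled — the matrix arrives however the
  user's pipeline left it.
* A candidate setting that fails (e.g. infeasible perplexity for n) is
  recorded, warned about, and excluded from the minimization rather than
  aborting the sweep.
* Grids must be strictly increasing; percentile bounds are validated; a
  null in which every score is undefined raises rather than classifying.

## Known limitations

* Scores compare one embedding against one pre-embedding; no stability
  analysis across random seeds or bootstraps is performed.
* A single gene-wise permutation defines the null (matching the method's
  design); the permutation seed is exposed for users who want to check
  sensitivity.
* The learning rate, random seed and other embedder knobs are not
  optimized — only perplexity (t-SNE) and n_neighbors/min_dist (UMAP).
* KNC requires cluster labels; no clustering is performed internally.
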