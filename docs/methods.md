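# Methods

## The annotation model

`acam` assigns a cell-type label to every cell of an scRNA-seq expression
matrix using only a marker-gene table (cell type → known marker symbols for
one species and tissue) as prior knowledge. The workflow rests on two
assumptions: (i) a cell type's marker genes are highly expressed in cells of
that type and comparatively weakly elsewhere, and (ii) cell groups that
*several different clustering algorithms unanimously agree on* are reliable
enough to annotate as a unit, while cells the methods disagree about are
better labeled afterwards by proximity.

The stages:

1. **Preprocessing.** Counts are size-factor normalized — each cell's column
   is rescaled so its total equals the median per-cell total — and log(1+x)
   transformed. The matrix is restricted to the union of marker genes;
   all-zero gene rows are dropped, and cells with zero expression across
   every marker gene are labeled `unknown` and removed (they carry no usable
   signal for a marker-based method). The resulting matrix X is M marker
   genes × n retained cells.

2. **Representative clusters.** Five clustering backends each produce a
   partition C_i of the cells. A pairwise ARI matrix R(i,j) = ARI(C_i, C_j)
   is built; for each method the variance of its off-diagonal row is
   computed, and the minimum-variance method — the one agreeing most evenly
   with everyone, hence adding least diversity — is removed (ties go to the
   earliest backend). The four survivors' co-clustering relations are
   intersected: cells u,v are joined in the consensus graph iff they share a
   cluster in *every* retained partition, equivalently iff the summed binary
   co-membership matrix equals 4. Because unanimity means "identical label
   tuple", this graph is a disjoint union of cliques. Louvain communities of
   the graph with size strictly greater than a threshold (default 10) become
   the representative clusters P_1..P_C; smaller communities join the
   leftover pool.

3. **Cluster annotation.** Each P_c is contrasted against all remaining
   cells U−P_c. The target group is oversampled with replacement to the
   adversarial group's size (each original cell kept at least once); genes
   whose mean log expression in the original cluster is not strictly above
   the complement mean are removed, since a marker of this cluster's type
   must be up-regulated in it. A gradient-boosted ensemble of depth-1 trees
   with a hinge objective is fit to the binary problem; one clean threshold
   split on a marker gene is exactly what a stump expresses, which is why
   the ensemble concentrates gain on true markers. Per-gene total-gain
   importances w_m are summed over each type's marker set,
   Score_t = Σ_{m∈G_t} w_m, and the cluster takes argmax_t Score_t (ties to
   the lexicographically smallest type name). A cluster with no up-regulated
   gene or an all-zero importance vector is labeled `unassigned`.

4. **Propagation.** All retained cells are projected to 2-D with UMAP from
   the marker matrix; each leftover cell takes the majority label of its k
   nearest representative-cluster cells there (k = 1 by default, i.e. the
   single nearest annotated cell). Representative labels are never modified.

5. **Evaluation** (when true labels are provided): accuracy, balanced
   accuracy (mean per-class recall), macro F1 as the *harmonic mean of
   macro-averaged precision and macro-averaged recall* (note: not the mean
   of per-class F1 scores; a flag exposes that alternative), and the
   multiclass Matthews correlation coefficient computed from the confusion
   matrix marginals. Rows index the true label, columns the prediction;
   `unknown`/`unassigned` are ordinary labels and count as errors unless
   true.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `threshold` | 10 | minimum representative-cluster size (strictly greater); raise on large datasets, lower below ~200 cells |
| `k` | 1 | neighbors for label propagation in the embedding |
| backends | 5 built-ins | Leiden on a PCA kNN graph; k-means on 2-D t-SNE; k-means, Gaussian mixture, and Ward on PCA; k-based methods pick k by a silhouette scan over 2..10 |
| booster | 100 rounds, η = 0.3, depth 1, hinge | only depth and objective define the method; the rest are the booster's defaults |
| UMAP | 15 neighbors, min_dist 0.1 | clamped with a warning when cells are fewer |
| `resolution` | 1.0 | Louvain resolution; nearly irrelevant on the near-clique consensus graphs the unanimity rule produces |

A single global seed fans out to per-stage seeds through a CRC32 hash of the
stage name, so each stage is independently reproducible and rerunning one
stage from exported artifacts (e.g. `--partition-file`) is bit-stable.

## Design choices where the design was open

- **Size factor** = median of per-cell totals, then log1p; the simplest
  depth correction consistent with the workflow, recorded in the
  `normalization` tag. Zero-total cells are dropped at this stage and folded
  into the `unknown` output — they satisfy the zero-marker rule trivially.
- **Row variance excludes the diagonal.** The constant 1s on the diagonal
  shrink every row's variance identically in expectation but can change the
  argmin at small method counts; disagreement *among peers* is what the
  selection is meant to measure. `include_diagonal=True` restores the
  alternative.
- **Prefilter means use the original cluster**, not the oversampled
  multiset: uniform oversampling leaves the expected mean unchanged, and
  using originals removes seed dependence from a deterministic filter.
- **Importance measure is total gain** (config-exposed): gain is the
  canonical split-quality measure and matches the marker intuition of large
  clean splits.
- **Oversampling target** is max(|P_c|, |U−P_c|): when a cluster already
  holds the majority of cells it is used as-is rather than shrunk.
- **Propagation runs in the 2-D embedding** (reduce, then classify), with a
  `propagate-space`-style alternative available by passing expression
  coordinates; distance ties break to the lowest cell index, vote ties to
  the smallest label, both deterministic.

## What the synthetic generator emulates — and what it does not

The generator plants T cell types with disjoint (optionally overlapping)
marker sets: counts are negative binomial (size = `dispersion`; variance
μ + μ²/r) with per-gene baseline mean, multiplied by `marker_fold_change`
for a type's markers in that type's cells, scaled by lognormal per-cell
library-size factors of a given CV, then thinned by independent dropout.
This reproduces the overdispersion, sparsity and depth variation that make
droplet data hard, and exactly the marker-elevation assumption the method
relies on. It does **not** model batch effects, continuous trajectories,
doublets, ambient RNA, or correlated gene modules — so passing tests
demonstrate correctness of the machinery and recoverability under the
stated noise model, not performance on real tissues.

Default generation conditions (3 types × 150 cells, 10 markers/type, 200
background genes, fold 10, baseline mean 2, dispersion 2, dropout 0.2,
library CV 0.1) give a dataset where a naive marker-mean classifier already
reaches ≥ 99% accuracy, establishing that the fixture is informative before
the pipeline is judged on it. Problem sizes in the test-suite and the
reproduction script (450–1500 cells, ≤ 330 genes) were chosen as the
smallest at which every stage — consensus graph, Louvain, boosting,
UMAP — operates in its intended regime.

## Numerical notes and limitations

- ARI uses the standard permutation-model (Hubert–Arabie) formula via
  scikit-learn; exact mathematical ties in row variances are possible (e.g.
  several identical partitions) and resolve to the earliest backend.
- The gene prefilter uses a strict `>`, so a gene expressed identically
  everywhere is removed.
- Communities produced by Louvain on a disjoint-clique graph equal the
  cliques; the seed only matters on graphs with inter-community edges, which
  the unanimity rule rarely produces.
- Rare populations below the size threshold are never representative
  clusters and inherit labels by proximity — a known limitation for rare
  cell types, as is the absence of any novel-type discovery: every cell is
  forced into a known type unless it expresses no marker at all.
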