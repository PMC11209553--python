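# Methods

## The post-integration data model

A `PiObject` represents one clustering level of a single-cell dataset: a
sparse nonnegative genes × cells expression matrix (stored internally as an
AnnData, cells × genes), a cell table (`cell_id`, `sample_id`, `group`,
`cluster`, all required and non-missing, `cell_id` unique), named per-cell
reductions, named neighbor graphs, analysis slots (`exp_freq`, `markers`,
`ds`, `cell_prop`), and links to a parent and to named children. A child is
a subclustering of a subset of its parent's cells; child cells keep their
parent cell ids, so all cross-object operations key by `cell_id` while each
object keeps its own canonical cell order. Children may carry a gene
subset; cross-level gene operations intersect by gene identifier.

`resolve_labels(root, level)` flattens the tree: each cell gets the deepest
available label at or above the requested depth (`0` = the root's own
clustering, `"leaf"` = full descent); cells never subclustered keep their
root label. Resolution is idempotent and depth-monotone — deeper labels
refine, never cross, shallower ones. Overlapping children are an error
unless the caller passes an explicit priority order (earlier names win);
the expected design is disjoint compartments.

Serialization is one directory per object (MatrixMarket matrix, TSV
metadata and tables, CSV reductions, triplet-TSV graphs, JSON manifest),
nested children as subdirectories — language-agnostic and diff-able.
Distances and coordinates are written with round-trip precision
(`repr`/`%.17g`) and read with correctly-rounded parsing, so write→read is
bit-exact.

## Subcluster re-projection

Given a root object and attached subclusterings, the algorithm produces one
neighbor graph — and from it one 2-D embedding — that shows subcluster
granularity on the total-cell map.

1. **KNN.** Exact K-nearest neighbors (brute force, Euclidean) on each
   object's chosen reduction, self excluded, distance ties broken by cell
   order. One K (default 20) is used for parent and children. Exactness
   keeps graph construction fully deterministic; approximate backends are
   deliberately out of scope as a correctness surface.

2. **Rescaling.** Child distances are multiplied by s = A_p / A_c, where
   A_c is the mean neighbor distance in the child graph and A_p the mean
   parent neighbor distance over edges with *both* endpoints in the child's
   cell set. This aligns the child's distance scale with the parent's in
   the region the child occupies; the ratio is invariant to uniform scaling
   of the child's coordinates. If no parent edge is internal to the set,
   edges with at least one endpoint inside are used; if none touch it,
   s = 1 with a warning. All child distances zero is a degenerate-scale
   error. Retained parent edges are *not* rescaled — scaling aligns the
   child to the parent, not vice versa.

3. **Merge.** K1 = round(w·K), rounding half away from zero, with
   w ∈ [0, 1] (default 1). For each cell in a subcluster: walk its parent
   neighbor row in rank order and keep up to K1 neighbors whose
   *parent-level* cluster differs from the cell's own (these cross-cluster
   edges carry the global structure); K1 is a cap, not a quota — an
   interior cell with few cross-cluster neighbors fills the shortfall from
   its subcluster graph. The remaining K − r slots are filled with the
   cell's nearest subcluster neighbors. A neighbor reachable through both
   graphs is kept once, at the smaller of the two distances, with the
   provenance of the kept copy. The row is sorted ascending by distance —
   ties broken by parent-provenance first, then neighbor order — and
   truncated to K. Cells in no subcluster keep their parent rows verbatim
   (a hard guarantee, tested bit-exactly). Rows shorter than K can occur
   only when candidates run out, and are recorded with a warning.
   Subcluster cell sets must be mutually disjoint.

4. **Embedding.** The merged directed rows are handed to the standard
   fuzzy-simplicial-set construction (which applies its usual fuzzy-union
   symmetrization) and to the stochastic-gradient layout, with neighbors
   *never* recomputed from coordinates. A single integer seed controls the
   layout only; with a fixed seed and serial execution the embedding is
   bit-reproducible. Layout defaults: min_dist 0.1, spread 1.0, 200
   epochs, spectral initialization (component-wise for disconnected merged
   graphs).

Recursion realizes multi-level integration: a child that itself has
children is re-projected first, and its merged graph stands in for its KNN
graph in the parent's merge.

Setting w = 0 removes all parent-derived edges from subclustered rows
(maximal subcluster separability); w = 1 retains all available cross-cluster
parent edges (strongest global connectivity). The retained cross-cluster
edge count is non-decreasing in w.

## Quantification

* **Expression frequency**: fraction of cells per cluster with raw value
  strictly > 0 — no minimum-count threshold, so the statistic is invariant
  to any monotone positive rescaling.
* **Markers**: one-vs-rest two-sided Wilcoxon rank-sum per gene; effect =
  log2 fold change of means (pseudo-offset 1e-9); BH adjustment across
  genes within each cluster; ranking by adjusted p, then effect. Clusters
  under 3 cells are skipped with a warning.
* **Pseudobulk / differential state**: raw counts are summed per
  (sample, cluster); columns are CPM-normalized, log2(x+1)-transformed, and
  compared per gene with a two-sided Welch t-test between groups (≥ 2
  samples per group required — sample-level replication is the point of
  pseudobulk); BH across genes within the cluster. Zero-variance genes get
  t = 0, p = 1.
* **Conditional proportions**: counts of each target cluster divided by the
  reference population's count, per group (pooled) or per sample
  (unpooled). The reference is the object itself, any ancestor, or a
  labelled subset of an ancestor; containment is enforced. Tables carry
  counts and denominators, so the chain rule
  prop(subset | total) = prop(subset | compartment) × prop(compartment | total)
  holds exactly in rational arithmetic. Between-group testing (unpooled
  only) is a two-sided Wilcoxon rank-sum on per-sample proportions, BH
  across clusters in the table. The tests are transparent defaults chosen
  for rank-based robustness at small sample counts; both are deliberately
  simple rather than compositional or mixed-model.

## Silhouette evaluation

Silhouette width s(i) = (b(i) − a(i)) / max(a(i), b(i)) with Euclidean
distance, computed exactly on all cells of the named (2-D) embedding — no
subsampling. Cells of singleton clusters get width 0 by convention, with a
warning. `compare_embeddings` reports per-cluster means before/after plus
deltas and can restrict to subclustered or untouched cells, reflecting the
two regimes expected of a good re-projection: improved subcluster
separability, near-unchanged main clusters.

## Synthetic fixtures

The generator emulates exactly the situation the toolkit targets. Cells
get latent coordinates in 10 dimensions: main clusters are well-separated
Gaussian blobs (separation 30, unit within-cluster spread); one main
cluster contains subpopulations offset by `sub_separation` (default 4, i.e.
overlapping at KNN scale) in random directions, the last one rare (3% of
its compartment). The parent's "pca" reduction is the latent space plus
small noise; its "umap" reduction places mains on a circle and shows
subpopulation offsets only through a fixed rank-2 projection — so sublabels
overlap there, as on a real total-cell embedding, unless separation is made
extreme. Each child carries a fresh PCA of its own cells' latent
coordinates (optionally at a different scale), emulating an independently
computed subcluster reduction. Counts are gamma–Poisson (dispersion 0.5,
~2000 counts/cell over 200 genes) with 5 planted marker genes per cluster
(8-fold) and an optional planted group effect for differential-state tests.
The design is 8 + 8 samples in two groups (6 + 6 for the differential-state
plan), with group-dependent composition, 1200 cells by default.

Dedicated light simulators cover proportion testing: direct per-sample
proportion draws (Gaussian around group means) for power/calibration, and a
compartment-shrinkage fixture in which the T compartment drops from ~45% to
~18% of cells between groups while its internal composition stays constant
— the situation (e.g. lymphopenia) where the choice of reference population
reverses conclusions.

What the generator does **not** emulate: batch effects, doublets, ambient
RNA, gene–gene correlation beyond cluster structure, library-size variation
between samples. Passing tests therefore demonstrate algorithmic
correctness and the intended qualitative behaviours, not robustness to
every artifact of real data.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale, chosen to exercise every
code path while keeping the default suite fast: 400–1200-cell hierarchies,
K = 10–20, merge-oracle instances of 30–100 cells across
w ∈ {0, 0.25, 0.5, 0.75, 1}, silhouette oracles at ≤ 50 points, 100–200
simulation replicates for the proportion-test properties, and 5 seeds for
embedding-level claims. Oracle comparisons for the merge are bit-exact by
construction (both paths consume identical inputs and apply the same
deterministic rule); silhouette agreement is asserted at 1e-12.

## Known limitations

* The merge treats "different cluster" at the parent's label level only —
  the only level defined for all candidate neighbors.
* Proportions use plain count ratios; strongly compositional designs may
  warrant log-ratio models, which are out of scope.
* The embedding stage is UMAP-only; alternative layouts would need their
  own precomputed-neighbor contract.
* Exact KNN is O(n²) per object; the intended regime is the desk-to-atlas
  scale where reductions fit in memory. An approximate backend could be
  added, but correctness guarantees are stated for the exact path.
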