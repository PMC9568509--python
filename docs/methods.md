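# Methods

This note documents the models, algorithms, parameter choices, and known
limitations of `treecap`, in the spirit of the methods documentation of
packages like scanpy or statsmodels. It states no empirical number that the
test suite or `scripts/acceptance.py` does not itself compute.

## Per-dataset trajectory model

A dataset is a counts matrix X (n cells × m genes). Preprocessing follows
standard scRNA-seq practice:

* **Filtering** removes cells expressing fewer than `min_genes` genes and
  then genes expressed in fewer than `min_cells` of the remaining cells
  (defaults 200 and 3 in the file-based runner; library calls default to no
  filtering so the caller controls it). Filtering is one pass each,
  cells first; it is idempotent.
* **Normalization** scales every cell to the same total (`target_sum`,
  default the median per-cell total) and applies log1p. Externally
  normalized matrices that contain negative entries can first be passed
  through per-gene min–max scaling (`scale_min_max`), mapping constant
  genes to 0.
* **Highly variable genes** are ranked by normalized dispersion: dispersion
  = variance/mean of de-logged expression, z-scored within 20
  equal-frequency bins of the gene mean (genes sorted by mean, ties by
  index, `np.array_split` into bins; a bin with zero spread contributes 0).
  Selection is either top-`n_top` or all genes above a cutoff.
* **PCA** is exact (full SVD) on the centered log expression of the
  selected genes, with a deterministic sign convention (the
  largest-magnitude loading of each axis is positive). Default p = 50.
* **kNN graph**: directed k-nearest-neighbor lists in PC space (ties broken
  toward the lower cell index), mutualized by union into an undirected
  graph weighted by Euclidean distance. Union rather than intersection
  keeps the graph connected more often. Note that the union graph
  guarantees a minimum degree of k but no 2k upper bound — a hub can
  appear in more than k neighbor lists.
* **Clustering** is Leiden community detection (RBConfiguration quality at
  resolution `resolution`, default 1.0; seed recorded, labels renumbered by
  first appearance so numbering is reproducible). The partition is computed
  on the unweighted graph: a modularity-type objective expects similarity
  weights, and distances would invert that meaning.
* **Centroids and tree**: each cluster is summarized by a virtual cell of
  coordinate-wise medians, both in PC space and in log-expression space
  over all genes shared between the two datasets (not only HVGs — the
  alignment cost works in the high-dimensional expression space). The
  trajectory is the minimum spanning tree over centroids with Euclidean
  distances between PC medians (Kruskal with deterministic tie-break by
  (weight, min id, max id)), oriented away from a root cluster. The root
  is supplied by the user (for real data, from marker genes); the automatic
  fallback uses the cluster containing the expression-space diameter
  endpoint, or — for ground-truthed synthetic data — the cluster with
  minimal median simulation time. MST distances use PC medians; the
  expression medians are reserved for the alignment cost.

Cycles and disconnected trajectories are out of scope: the model is a
rooted tree.

## Tree alignment

An alignment of two rooted unordered labeled trees is obtained by
inserting gap nodes (`#`) into both until they are isomorphic and
overlaying them; its cost is the sum of label-pair costs

* γ(i, j) = 1 − Spearman(xᵢ, xⱼ) for two cluster expression-median vectors
  over the shared genes (average ranks for ties; range [0, 2]);
* γ(i, #) = γ(#, j) = δ, the gap penalty, default δ = 1.

γ is a metric on the label alphabet; the pair (#, #) is excluded. Zero
rank variance (a constant expression vector) makes Spearman undefined and
is an error; the pipeline therefore drops constant cells up front and
works with continuous medians, which are constant only in degenerate
inputs.

The optimal alignment distance is computed by the bounded-degree dynamic
program over (subtree, subtree) pairs and (child-forest subset, child-forest
subset) pairs:

* tree level — three cases: match the two roots and align their child
  forests; gap the root of one tree and align the entire other tree
  against one of its child subtrees (and symmetrically);
* forest level — over subset pairs (A, B): peel off a matched subtree
  pair, or gap the root of a subtree in A and align its child forest
  against some subset B′ ⊆ B (and symmetrically). Subsets are encoded as
  bitmasks; memoization is keyed by (parent node pair, maskA, maskB) since
  child subsets are local to the parent pair.

Base cases: D(θ, θ) = 0 and the all-gap cost of a subtree is its size
times δ. For bounded degree the table has O(|T₁||T₂|) tree states (the
test suite checks the quadratic scaling on chains). Degrees above
`max_degree` (default 10) raise an error: the subset enumeration is
exponential in the degree and the general unordered problem is MAX
SNP-hard, so there is no safe silent fallback.

Traceback is deterministic: cases are tried in the order listed, and
within the forest recursion the lexicographically smallest expansion wins.
The result is an aligned tree whose nodes are (cluster-or-gap,
cluster-or-gap) pairs; projecting it onto either side (dropping gap nodes,
contracting their edges) reproduces the corresponding input tree exactly —
this invariant is tested. An empty tree on either side yields the all-gap
alignment of the other tree (distance |T|·δ) rather than an error, which
keeps metric-style properties (identity, symmetry, upper bound) testable.

Correctness is established against a brute-force oracle that enumerates
every legal gap-insertion/overlay structure recursively (anchored on the
fate of the first tree of a forest: matched, gapped-and-adopting, or
adopted-by-a-gap), with no memoization and an independent nested-tuple tree
representation. One subtlety: the three-case tree recursion does not
generate structures in which a gapped root's partner gap node adopts
several of its children, but such structures can never be strictly optimal
when γ(i, j) ≤ 2δ — guaranteed here since γ ≤ 2 and δ = 1 — so the DP and
the (more permissive) oracle agree; the oracle equivalence test covers 200
random tree pairs.

## Cell-level alignment

For each root-to-leaf path of the aligned tree, the member cells of each
dataset (all cells labeled with the path's clusters) are ordered by
diffusion pseudotime:

* **Start cell.** Among the cells of the path's first (root) cluster, the
  cell with the longest expression-space distance to any other cell of the
  dataset (the diameter endpoint; the ambiguous "longest distance" is read
  as max–max, not max–min). Ties go to the lower cell index. On
  ground-truthed data the pipeline instead anchors at the root-cluster
  cell of minimal simulation time, matching the benchmark convention of a
  time-zero start.
* **DPT.** A Gaussian-kernel transition matrix on the path cells is
  spectrally decomposed and pseudotime is the accumulated-transition
  distance from the start cell over the top `n_dcs` (default 10)
  non-stationary components; the computation is delegated to scanpy
  (`neighbors(method="gauss")`, `diffmap`, `dpt`). The operation's default
  truncates the kernel to the kNN graph and requires that graph to be
  connected (a disconnected input is an error listing component sizes).
  The pipeline opts into the *dense* adaptive kernel (`dense=True`) with a
  30-neighbor scale: at the cell densities left after splitting a dataset
  in half, the truncated kernel loses noticeable rank fidelity, while the
  dense kernel recovers a noiseless 1-D gradient exactly. Neighbors are
  computed in the PCA embedding. If a path's cells fall into several kNN
  components, the pipeline keeps the component containing the start cell
  and warns, rather than aborting the whole run.
* **DTW.** The two pseudotime orderings are aligned by classical dynamic
  time warping: steps {(1,0),(0,1),(1,1)}, boundary-anchored, local
  distance 1 − Spearman between the two cells' log expression over the
  intersection of the datasets' HVG lists (Euclidean available via
  `metric="euclidean"`). Ties in the traceback prefer the diagonal step.
  The DP is validated against exhaustive enumeration of all monotone
  boundary paths.
* **Gene kinetics.** Genes above a normalized-dispersion cutoff (default
  1.0) in either dataset — computed on the path's cells, independently per
  path — are profiled along the warped alignment: both aligned series are
  min–max scaled, a least-squares line is fitted against the normalized
  aligned position in [0, 1] (so slopes are comparable across genes), and
  the gene is grouped by slope signs: `up_up`, `up_down`, `down_up`,
  `down_down`, or `flat` (an exactly zero slope). The reported similarity
  per gene is the DTW cost of its two aligned series under
  absolute-difference local cost. A set difference across paths flags
  genes selected for exactly one path as candidate cell-type-specific
  programs.

## Metrics

* **Normalized alignment distance.** D(T₁, T₂) decomposes into d_M (sum of
  γ over matched pairs) + d_U (δ times the gap count). With M matched and
  U unmatched pairs, `d_norm = α·d_M/(M+1) + (1−α)·d_U/(U+1)`, α = 0.9.
  The weighting reflects that with δ = 1 the per-node gap term is bounded
  by 1 while the matched term is the essential signal. d_norm is strictly
  increasing in each cost part and zero for a tree aligned with an exact
  copy of itself.
* **ATC.** A lineage is a root-to-leaf path of the aligned tree. Per
  lineage and per dataset, Spearman's ρ between the member cells' true
  simulation time and their inferred pseudotime is scaled to [0, 1] by
  (ρ+1)/2; the two datasets' values are averaged, then the mean over all
  lineages is the ATC score. A constant pseudotime series has undefined ρ
  and is scored as ρ = 0 (i.e. 0.5) with a warning. The score is invariant
  under strictly monotone transforms of either series, and an independent
  random prediction concentrates at 0.5 — the null value the acceptance
  script recomputes.

## Synthetic benchmark generator

The generator is a transparent branch-program simulator, not a
gene-regulatory-network model: its purpose is data with known simulation
time, branch structure, and tunable noise.

* **Backbone**: a rooted tree; the default is a binary tree with three
  branch points and four leaves (root → {B, C}, B → {leaf1, leaf2},
  C → {leaf3, leaf4}), all edges of unit time length.
* **Cells** are assigned to edges in a balanced round-robin and placed
  uniformly along their edge; `sim_time` is the distance from the root and
  `branch_label` the edge's child node.
* **Expression**: each edge owns `n_branch_genes` (default 30) dedicated
  genes whose program mean ramps linearly from a baseline (1.0) to an
  amplitude drawn once per gene from U(8, 20) along the branch, and stays
  at full amplitude in all descendant branches — so expression is smooth
  and monotone along every root-to-leaf path and lineage identity
  persists. The remaining genes are housekeeping with constant means
  U(1, 4). Counts are Poisson draws around the program mean times a
  lognormal factor (`noise_sd_base`, default 0.3) with Bernoulli dropout
  (default 0.1). Defaults give on the order of 800 counts per cell over
  260 genes — chosen once as a realistic desk-scale depth at which
  biological ordering is recoverable but not trivial. Deterministic per
  seed.
* **Perturbations**: random disjoint half-splitting (optionally stratified
  by branch), additive Gaussian noise on log counts (sd 0 is the exact
  identity; raw counts untouched), and node removal on inferred trees — a
  leaf disappears, an internal node's children reattach to its parent, a
  removed root promotes its lowest-id child and reattaches the siblings
  beneath it (the reattachment rule is this package's convention; nothing
  canonical exists for re-rooting after deletion).

What the generator does *not* emulate: regulatory kinetics and mRNA
splicing dynamics, batch effects, doublets, ambient RNA, cell-cycle
structure, or realistic gene–gene correlation beyond shared branch
programs. Passing benchmarks on this data therefore demonstrates the
correctness and robustness of the alignment machinery, not performance on
arbitrary real tissues.

## Benchmark protocols and problem sizes

The packaged benchmarks run at desk scale, chosen to finish in minutes on
one CPU while preserving the qualitative behavior:

* *Self-split recovery*: one clean 1000-cell simulation, split into
  disjoint halves, full pipeline; every terminal branch label must be
  matched across the halves and every lineage must conserve the true
  ordering (score ≥ 0.9).
* *Noise degradation*: 10 replicates per noise sd ∈ {0, 1, 2, 3} at 600
  cells; the median normalized distance must be non-decreasing in sd and
  the median ATC at sd 3 must fall below the medians at sd ≤ 1.
* *Topology perturbation*: 10 replicates at 600 cells; aligning a
  perturbed tree against its original, root removal must cost strictly
  more (median d_norm) than leaf removal.
* Split benchmarks cluster at resolution 2.0: with only ~300 cells per
  half, the default resolution merges sibling branches around branch
  points into one cluster, which blurs lineage membership; the finer
  partition keeps branch-point clusters coherent.

## Numerical choices and degenerate inputs

* All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`, leidenalg's seed, scanpy's fixed
  `random_state`); fixed seeds reproduce byte-identical JSON/TSV outputs.
* Spearman computations use average ranks for ties; cross-correlation
  matrices are computed as Pearson on rank-transformed rows.
* DP ties break deterministically (documented per algorithm above); kNN
  distance ties break toward the lower cell index; HVG ranking ties break
  toward the earlier gene.
* Degenerate inputs raise informative errors rather than guessing: empty
  files, duplicated identifiers, cells with zero totals, constant vectors
  where a correlation is required, disconnected path graphs, degree-bound
  violations, removing the root of a single-node tree.

## Limitations

* The tree-level alignment is global; local alignment, tree inclusion, and
  general graph trajectories are out of scope, as is tree *edit* distance
  (a different optimization problem).
* Cluster-path lineages inherit clustering errors: cells of a sibling
  branch that fall into a shared progenitor cluster dilute the
  conservation score, which is a property of the model, not a bug in the
  metric.
* The degree cap makes star-like trajectories (one hub cluster with many
  spokes) unalignable by design; re-cluster at lower resolution instead.
* MAGIC-style denoising is not re-implemented; the readers accept an
  externally denoised/normalized matrix (`scale_min_max` plus the
  `log_counts` layer hook).
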