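# treecap

Comparative analysis of single-cell pseudotime trajectories.

Two scRNA-seq experiments that profile the same differentiation process —
two replicates, two donors, two species with orthologue-renamed genes —
each yield their own branching trajectory. `treecap` aligns the two
trajectories at two levels so that cell states and gene kinetics can be
compared across datasets:

1. **Cluster level.** Each dataset is reduced to a rooted *trajectory
   tree*: PCA on highly variable genes, a kNN cell graph, Leiden
   clustering, one *centroid* (coordinate-wise median virtual cell) per
   cluster, and a minimum spanning tree over centroids rooted at a chosen
   cluster. The two trees T₁, T₂ are then aligned globally by inserting
   gap nodes (`#`) until they become isomorphic, minimizing the total label
   cost

   γ(i, j) = 1 − corr(xᵢ, xⱼ)  for two cluster expression vectors
   (Spearman), and γ(i, #) = γ(#, j) = δ (gap penalty, default δ = 1).

   The minimum-cost overlay D(T₁, T₂) is found by a dynamic program over
   subtrees and child-forest subsets — exact, and polynomial for trees of
   bounded degree (the unrestricted unordered problem is MAX SNP-hard, so
   degrees above a cap raise an error rather than an approximation).

2. **Cell level.** For every root-to-leaf path of the aligned tree, the
   member cells of each dataset are ordered by diffusion pseudotime (DPT)
   from a data-driven start cell, and the two orderings are aligned by
   dynamic time warping (DTW) with local distance 1 − Spearman over the
   shared highly variable genes. Per-gene kinetics along the warped path
   are fitted with least-squares lines and grouped by slope signs
   (up/up, up/down, down/up, …) to flag conserved versus diverged programs.

Two metrics summarize an alignment:

* **normalized alignment distance** `d_norm = α·d_M/(M+1) + (1−α)·d_U/(U+1)`
  where d_M, d_U split the alignment distance into matched-pair and
  gap-pair parts and M, U count those pairs (α = 0.9); lower is better.
* **average trajectory conservation (ATC)**: per lineage, Spearman's ρ
  between true simulation time and inferred pseudotime scaled to [0, 1] by
  (ρ+1)/2, averaged over the two datasets and over lineages. 1.0 is perfect
  recovery; 0.5 is chance.

A fully ground-truthed synthetic benchmark generator (branching
differentiation with per-cell simulation time and branch identity, random
disjoint splitting, additive Gaussian noise, tree-topology perturbations)
makes the whole pipeline testable without downloads.

## Worked example

Simulate a 1000-cell, four-leaf branching dataset, split it into two
disjoint halves, and align the halves end to end:

```python
import treecap as tc

cfg = tc.SimulationConfig(n_cells=1000, seed=0)
res = tc.split_benchmark(cfg, split_seed=0, compute_dtw=True,
                         dispersion_cutoff=0.5)

print(res.manifest["n_clusters"])          # [7, 7]
print(res.tree1.to_newick())               # ((2,4)0,1,(5)6)3;
print(round(res.aligned.distance, 4))      # 3.5255
print(res.aligned.matched_pairs,
      res.aligned.unmatched_pairs)         # 6 2
print(round(res.d_norm, 4))                # 0.2628
print(round(res.atc, 4))                   # 0.9657
for lin in res.lineages:
    print(lin.name, round(lin.conservation.score, 3))
# 3-0-2|6-0-4 0.953
# 3-0-4|6-0-3 0.953
# 3-1|6-1-5   0.979
# 3-6-5|6-1-2 0.978
```

Reading: each half was clustered into 7 clusters; the tree alignment
matched 6 cluster pairs and needed 2 gaps, giving a normalized distance of
0.26. The four aligned root-to-leaf paths correspond to the four simulated
terminal fates; each conserves the true temporal ordering with a score
above 0.95 (1.0 = perfect). With `compute_dtw=True`, `res.lineages[i].dtw`
holds the warping path and `res.lineages[i].kinetics` the per-gene slopes
and groups — in this run 38–43 genes per lineage rise in both datasets
("up_up": the branch programs), and the genes that fall in both datasets
are the relatively down-regulated non-activated programs.

The same workflow is scriptable from the shell:

```bash
treecap simulate --n-cells 1000 --seed 0 -o sim.h5ad
treecap preprocess data.csv --min-genes 200 --min-cells 3 -o prep.h5ad
treecap trajectory prep.h5ad --root 4 -o tree1.json --save-annotated ann1.h5ad
treecap align --tree1 tree1.json --tree2 tree2.json -o aligned.json
treecap dtw --aligned aligned.json --data1 ann1.h5ad --data2 ann2.h5ad \
            --path-index 0 -o dtw_out/
treecap eval --aligned aligned.json --alpha 0.9
treecap run --config run.yaml        # the whole pipeline from a YAML config
```

For real data, choose each tree root from biology (e.g. the cluster with
the highest stem-marker expression) and pass it as `--root` / `root1` —
the tool cannot infer biological directionality on its own.

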