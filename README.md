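# admixalign

Alignment of replicate mixed-membership clustering results for population
structure analyses.

Programs such as ADMIXTURE, Structure, and fastStructure model each
individual's genome as a mixture of K latent ancestral clusters and output a
row-stochastic N×K *membership matrix* Q. Replicate runs on the same data are
hard to compare directly because of three obstacles:

* **label switching** — any of the K! column permutations describes the same
  solution;
* **multimodality** — runs can converge to genuinely distinct solutions
  ("modes") that no relabeling reconciles;
* **varying K** — structure salient at one K relates to other K values by
  clusters splitting and merging.

`admixalign` resolves all three: it aligns all same-K run pairs optimally,
detects modes by community detection on the resulting similarity network,
aligns modes across K through anchor mode pairs, and renders the two summary
figures of the workflow — the multipartite graph of mode bar plots and the
alignment pattern graph that traces where each new cluster emerges. A
`compmodels` module compares per-model mode sets (e.g. ADMIXTURE vs
fastStructure) side by side, interleaved by K, flagging near-empty clusters.

## The optimization at the core

For a target matrix Q_t (smaller or equal K) and source matrix Q_s, a
matching assigns every source cluster to exactly one target cluster, covering
all target clusters; columns assigned to the same target are summed
(`merge`). The alignment cost and similarity are

    cost = ‖ Q_t − merge(Q_s) ‖²_F / (2N),      similarity = 1 − cost.

Row-stochasticity bounds cost to [0, 1]; cost 0 holds exactly when the two
runs are identical up to the matching, so a clean column split aligns across
K at cost 0. At equal K the optimum is a linear assignment over the K×K
matrix of column squared distances; for K_t < K_s the surjective matching is
found exactly either by a subset-partition dynamic program (small K) or by an
integer linear program (HiGHS), both verified against brute-force enumeration.

Modes are communities of the complete run network with edge weights
max(0, similarity − 0.5) (Louvain by default, Markov clustering optionally);
each mode is summarized by the entrywise mean of its members aligned to the
mode medoid. Across K, one *anchor mode pair* per adjacent pair of present K
values (the major modes, or the best-matching pair) fixes a single global
cluster labeling: each lower-K cluster's label is inherited by its closest
aligned child, and every other child receives the next unused label.

## Worked example

Generate a synthetic collection with a planted split hierarchy (K = 2..4,
eight replicate runs per K, Dirichlet noise, recorded label permutations),
then run the full pipeline:

```
admixalign simulate --out-dir runs --k-min 2 --k-max 4 --n-runs 8 --seed 5
admixalign pipeline --input-dir runs --labels-file runs/labels.txt --output-dir out
cat out/alignment_pattern.txt
```

which prints

```
K2M1-K3M1: 2,2,1 (anchor)
K3M1-K4M1: 3,1,2,3 (anchor)
```

Each line gives, for one cross-K mode pair, the global label of the parent
cluster that each child cluster aligns to (children in column order). Here
all 8 runs per K fall into one mode (`K2M1` = mode 1 at K = 2, and so on);
in `K2M1-K3M1: 2,2,1` two K = 3 clusters map onto cluster 2 — cluster 2
split in two when going from K = 2 to K = 3 — while cluster 1 passed through
unchanged. `out/modes.csv` reports each mode's size and within-mode
similarity (here sizes 8 and within-similarities ≈ 0.99, since the replicates
differ only by label switching and simulation noise), `out/crossk_graph.json`
holds every cross-K matching with its cost and similarity, and `out/plots/`
contains the multipartite and alignment-pattern figures. Every step
(`align`, `modes`, `acrossk`, `plot`) can also be run separately and produces
byte-identical artifacts, so any stage can be swapped for a custom tool with
compatible files.

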