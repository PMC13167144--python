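# Methods

This note documents the models, algorithms, numerical choices, and known
limitations of `admixalign`. It is written for users who need to know
exactly what the package computes, and why the open design points were
settled the way they were.

## 1. The cost functional

All alignment operations minimize one functional. Let Q_t be the target
membership matrix (N×K_t, the run with the smaller or equal number of
clusters) and Q_s the source (N×K_s, K_s ≥ K_t). A matching σ maps each
source cluster to exactly one target cluster and covers every target
cluster; `merge(Q_s)` sums source columns by their assigned target. Then

    cost(σ) = ‖ Q_t − merge_σ(Q_s) ‖²_F / (2N),    similarity = 1 − cost.

Properties that motivate this form:

* both Q_t and merge(Q_s) are row-stochastic, so each row contributes at
  most 2 to the squared Frobenius norm and cost ∈ [0, 1];
* cost 0 ⇔ the matrices agree entrywise after matching, so label-switched
  copies and exact column splits score a perfect similarity of 1;
* at equal K the functional separates over column pairs, reducing the
  optimization to a standard linear assignment problem.

Columns merged onto one target are **summed, not averaged**, so membership
mass is conserved and the "cluster splits in two" relation across K is a
zero-cost event — the semantics the alignment pattern graph visualizes.
Published alignment tools differ in their exact normalizations; this
package's functional is fixed as above and isolated in a single function
(`alignment.alignment_cost`), so substituting a different normalization is
a one-function change that leaves every optimizer untouched.

## 2. Solvers

**Equal K.** The K×K matrix of column squared distances is fed to the
Jonker–Volgenant solver (`scipy.optimize.linear_sum_assignment`). This is
exactly equivalent to the integer-programming formulation but O(K³).

**Unequal K.** The merged objective couples source columns assigned to the
same target through their Gram matrix, so the problem is a quadratic
semi-assignment. Two exact solvers are provided:

* *subset dynamic program* (default for K_s ≤ 10): the cost separates over
  target blocks, so a partition DP over subsets of source columns finds the
  exact optimum in O(K_t·3^{K_s}) with precomputed subset column sums;
* *integer linear program* (default above K_s = 10): binary variables
  x_{cd} with Σ_d x_{cd} = 1 and Σ_c x_{cd} ≥ 1, quadratic terms linearized
  by product variables y ≥ x_{cd} + x_{c'd} − 1, solved by HiGHS through
  `scipy.optimize.milp` at a relative gap of 1e-9; solutions are rejected
  if any nominally binary variable is further than 1e-6 from {0, 1}.

Both solvers, and the equal-K path, are verified against brute-force
enumeration of all bijections / surjective maps (the enumeration oracle
refuses K > 7) on hundreds of random instances in the test suite.

**Determinism.** Cost ties (differences ≤ 1e-9) are canonicalized to the
lexicographically smallest assignment vector: the DP reconstructs the
assignment greedily, testing smaller targets first; the LAP and ILP paths
re-solve with a fixed prefix to check whether a lexicographically smaller
choice still attains the optimum. Costs below 1e-15 are snapped to exactly
0, absorbing float residue introduced by row renormalization.

## 3. Mode detection

For the R runs at one K, all R(R−1)/2 optimal pairwise similarities form a
complete weighted network. Communities of this network are the modes.

**Edge weighting.** Modularity is invariant to uniform scaling of edge
weights, so community detection on raw similarities cannot distinguish a
collection of uniformly *similar* runs from uniformly *dissimilar* ones —
both give a single community. Edges are therefore weighted
w = max(0, similarity − 0.5), with zero-weight edges omitted. The shift is
a chance-level baseline, not a tuned cutoff: similarity 0.5 means half the
total membership mass disagrees after optimal matching, which is the
natural boundary between "mostly the same solution" and "mostly different".
With this weighting the two extremes behave correctly: identical-up-to-
permutation collections form one mode of size R, and mutually dissimilar
collections (all similarities ≤ 0.5) fall apart into R singletons.

**Algorithms.** Louvain (networkx implementation, default seed 42) is the
default; Markov clustering is provided as an alternative (expansion M²,
Hadamard inflation with exponent 2.0, column renormalization, pruning at
1e-12, convergence when the flow matrix changes by < 1e-8; clusters are the
connected components of the converged flow's support). Both are exposed via
`cd_method`. A `force_single_tol` override returns a single mode, skipping
community detection, when *every* pairwise dissimilarity 1 − similarity is
below the tolerance (e.g. 1e-6) — useful when minor disagreements are
acceptable for summarization even if the network has nominal structure.

**Summaries.** Modes are numbered by decreasing size, ties broken by higher
within-mode similarity and then smallest member run id; mode 1 at K = 5 is
"K5M1" (all user-facing labels are 1-based). The within-mode similarity is
the mean over unordered member pairs (1 for singletons). The consensus
representative is the entrywise mean of the members after aligning each to
the mode's *medoid* — the member with the highest total similarity to the
rest — then renormalizing rows. The medoid was chosen as the common
reference because it is deterministic and robust to outlying members; any
member would serve in the noise-free limit.

## 4. Cross-K alignment and global labels

Present K values are processed in ascending order; adjacent *present*
values are aligned directly, so gaps in K are handled without intermediate
levels. For each adjacent pair K1 < K2 an **anchor mode pair** is chosen:
either the major (largest) modes at each level, or the pair with the
highest cross-K similarity (`anchor_criterion`: `major` | `best`). The
anchor pair is aligned with the surjective matching; every other mode
reaches its level's anchor by an equal-K alignment of representatives, and
its cross-K matching is the composition through the anchor. Composition
(rather than independent pairwise cross-K alignment) guarantees a single
consistent labeling across the whole figure; the composed matchings' costs
are re-evaluated on the actual representatives, not composed. The one
consistency trade-off is that a composed matching need not be the
independent optimum for a non-anchor pair — it is exactly optimal whenever
the mode is a relabeling of its anchor, which the tests verify.

Global labels: the major mode at the smallest K takes labels 1..K_min in
its column order. Through each anchor matching, among the children of one
parent cluster the child whose membership column is closest to the parent's
(squared distance, ties to the lower index) inherits the parent's label;
all other children are *new* clusters and receive the next unused labels in
order of decreasing total membership. Exactly K2 − K1 new labels appear per
step, and a pattern edge is flagged "new" exactly when its child's label
does not exist at the parent's level. The synthetic split fixtures keep
60% of a split column's mass at the original position precisely so the
inheriting child is unambiguous (a 50/50 split would tie).

## 5. Visualization

Colors are a pure function of the global label (label ℓ → entry ℓ−1 of a
fixed 60-color palette: tab20 then tab20b then tab20c), so a cluster chain
keeps its color in every figure. Edge gray level in the multipartite graph
maps similarity 1 to black and the graph's minimum similarity to 0.8
luminance, linearly. Individual reordering groups individuals by their
population label and sorts each group by descending membership in the
group's dominant cluster (largest within-group column sum, ties to the
lower index) of a reference mode — the major mode at the largest K by
default, or the smallest K (`reorder_reference`). The sort is stable, so
the rule is idempotent on its own output. Bar plots always render every
individual; for very large cohorts a warning notes that rendering may be
slow, but data are never subsampled.

## 6. Model comparison

`compmodels` treats a "model" as an opaque tag (program, setting, or
downstream choice) and runs the complete single-model pipeline per model —
the per-model results are bitwise identical to running that model alone,
which the tests assert. For display, each non-reference model's modes are
aligned at equal K to the reference model's major mode at that K and
relabeled through the reference's global labels; representative values are
never modified. Clusters with mean membership below `empty_epsilon`
(default 0.01, configurable) are flagged as near-empty — the signature of
programs that encourage empty clusters at large K. Alignment across models
is done at the representative level (not on pooled runs) to preserve the
per-model independence property.

## 7. The synthetic generator

The generator emulates the study conditions of a replicate-run analysis:
a cohort of N individuals in labeled groups (default 6 groups × 10), each
group dominated by one cluster with mass 0.95 and the remainder spread
uniformly; per-run Dirichlet noise with concentration `noise_scale` × the
profile row (default 50, giving within-mode similarities ≈ 0.99); and a
recorded uniform random column permutation per run. Multimodal collections
plant each mode as a distinct group→cluster assignment map, drawn by
seeded rejection until every pairwise noise-free similarity is at most
`max_cross_similarity` (default 0.6) — this guarantees the planted modes
are not relabelings of each other. The defaults are set by the geometry of
the cost functional: with 0.95-dominant profiles at K = 3 the best
achievable cross-map similarity is ≈ 0.57, so planted modes sit just under
the 0.6 boundary; the fully dissimilar regime used for the R-singleton
extreme requires sharper profiles (0.98) and more groups (24) to push all
pairwise similarities below the 0.5 chance baseline. Split hierarchies
derive the K+1 base from the K base by dividing one seeded-random column
60/40 between its original position and a new rightmost column, so the
merged matrix reconstructs the parent exactly.

What the generator does **not** emulate: correlated noise across
individuals (real runs err systematically, not row-independently),
unbalanced group sizes, admixture clines within groups, convergence
failures, and between-K inconsistency other than clean splits. Passing
tests therefore demonstrate correctness of the alignment machinery under
controlled conditions, not that real collections of runs are this well
behaved; on real data modes are blurrier and within-mode similarities
lower (≈ 0.8 is common).

## 8. Pipeline, determinism, problem sizes

Every step reads and writes only open text artifacts (CSV, JSON, `.Q`), so
stages can be substituted by custom tools; the integrated pipeline calls
exactly the step functions and is byte-identical to stepwise execution.
Matrices are written at %.17g so files round-trip doubles losslessly; CSVs
use 12 significant digits. Rows whose sums drift from 1 by at most 0.05
(fixed-precision program output) are renormalized with a logged warning;
larger drift is rejected as corruption. Timing and config-hash metadata go
under `logs/`, outside the deterministic artifact set. Test and acceptance
problem sizes (N ≤ 200, R ≤ 50, K ≤ 8, plus one K = 40 scaling check) keep
the whole suite in the tens of seconds while exercising every code path;
they were chosen as the smallest sizes at which every phenomenon of
interest (multimodality, gaps in K, singleton shattering) still occurs.

## 9. Known limitations

* The cost functional is this package's documented choice; other alignment
  tools normalize differently, so absolute cost values are not comparable
  across tools (rankings of matchings typically are).
* Composed non-anchor cross-K matchings can be suboptimal for modes that
  are far from their level's anchor; the figures label such edges with
  their true (re-evaluated) cost, which makes the discrepancy visible.
* The 0.5 similarity shift for community detection is principled but
  fixed; collections whose genuine modes are mutually more similar than
  0.5 + ε are merged unless the network's relative structure separates
  them. Louvain on weighted graphs has no optimality guarantee.
* Structure output parsing extracts only the membership block; individual
  identifiers are not used to reorder rows, so all runs must list
  individuals in the same order.
* No statistical test for the number of modes is performed; mode counts
  are descriptive.
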