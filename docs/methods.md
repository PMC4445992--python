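# Methods

## Problem and model

Protein complexes appear in protein–protein interaction (PPI) networks as
densely interconnected vertex sets, and their members tend to share
functional annotation — but usually only in *some* of the three Gene
Ontology aspects (biological process Λ_p, molecular function Λ_f, cellular
component Λ_c), not all of them. This package detects (possibly
overlapping) complexes by estimating jointly:

* a **likelihood matrix** W ∈ [0,1]^{n×n}, where w_ij is the propensity of
  proteins i, j to be placed in the same complex, and
* a **preference vector** r_i = (r_ip, r_if, r_ic) per protein, nonnegative
  with r_ip + r_if + r_ic = 1, weighting how much each GO aspect counts when
  co-clustering protein i.

The inputs are the 0/1 adjacency indicator T, the topological similarity
matrix D (Jaccard index of open interaction neighborhoods) and the three
functional similarity matrices A_m (Jaccard index of term sets per aspect).
All similarity matrices are symmetric, have zero diagonals, and use the
convention that two empty sets have Jaccard 0 — absence of annotation is no
evidence of similarity. The estimation problem is

    max J(W, R) = Tr((W_T)ᵀ W_D W_T) + β Tr(Σ_m Wᵀ S_m) − ‖W‖_F² − ‖R‖_F²
    s.t. R1 = 1, R ≥ 0, 0 ≤ W ≤ 1

with W_T = T∘W, W_D = D∘W and S_m = [a_ij^m r_im]. The first term expands to
Σ_ij d_ij w_ij Σ_k w_ik w_jk t_ik t_jk: a pair scores when it has many
common interaction partners that are themselves co-clustered with both
endpoints (density). The second expands to β Σ_ij w_ij Σ_m a_ij^m r_im:
likelihood accrues to pairs similar in the aspects the row protein prefers,
and preference mass flows to aspects in which the protein resembles its
high-likelihood partners. The Frobenius terms penalize saturating W and
concentrate-free R. β weights the functional term; its default 1 is the
value that makes the trace form and the expanded form of the objective
coincide.

## Alternating optimization

Starting from W off-diagonal ~ U(0,1) and preference rows at the simplex
barycenter with ±0.01 jitter (a single seeded RNG stream; near-uniform
start avoids biasing any aspect), each iteration updates R with W fixed and
then W with R fixed:

**Preference step.** The rows of R are independent subproblems. Each is
solved with one primal–dual active-set step on the simplex: the step
direction is Δr_im = 0 for active nonnegativity constraints and
Δr_im = g_m − (Σ_{m'∉P} g_{m'})/(n_Λ − n_P + 1) otherwise, where g is the
gradient of J(r_i | W); the step length λ = min(1, min{r_im/−Δr_im : Δr_im
< 0}) retreats to the first nonnegativity boundary hit. A constraint is
treated as active when the component is ≤ 1e−12 **and** the unconstrained
direction would push it negative — the standard activation test, which
prevents oscillation at the boundary.

The printed direction formula does not exactly preserve Σ_m Δr_im = 0 (the
denominator carries a "+1"), so the row sum can drift off 1; rows are
renormalized whenever the drift exceeds 1e−9, and the number of
renormalizations is reported on the result object. A row annihilated to
zero (not observed in practice; possible only for degenerate directions) is
reset to the barycenter.

**Likelihood step.** With R fixed, each entry has a concave scalar
subproblem J(w_ij) = −w_ij² + c_ij w_ij with
c_ij = d_ij Σ_k w_ik w_jk t_ik t_jk + β Σ_m a_ij^m r_im. All entries are
refreshed simultaneously (a Jacobi sweep using only the incoming iterate on
the right-hand side), then clipped to [0,1]. The simultaneous sweep makes
the update deterministic and equivariant under protein relabeling;
Gauss–Seidel sweeps would be order-dependent. Every ordered pair is
updated, not only adjacent ones, because the functional term is nonzero for
non-adjacent pairs. W is *not* symmetrized during optimization — w_ij and
w_ji can differ because c_ij uses r_i only; symmetry is resolved at the
clustering stage.

**Modes.** The default mode, `"as-printed"`, applies the update formulas of
the original method description exactly as stated: gradient
g_m = −r_im + Σ_j w_ij a_ij^m, and new w_ij = clip(c_ij). These differ from
the exact derivatives of J by constant factors (the derivative of −‖R‖_F²
is −2 r_im, the gradient's functional sum should carry β, and the
stationary point of the scalar subproblem is c_ij/2). The alternative mode,
`"corrected-gradient"`, uses the exact forms; it is the mode under which
the finite-difference and grid-argmax consistency checks in the test suite
are meaningful. Both modes preserve feasibility at every iterate. The two
are kept side by side deliberately rather than silently "fixing" the
printed constants.

**Convergence.** Iteration stops when |J^{(l+1)} − J^{(l)}| ≤ δ or after
l_max iterations; non-convergence is flagged, not raised. Defaults
l_max = 100, δ = 1 are the recommended operating point. Monotone ascent of
J across full iterations is *not* asserted: the per-entry W subproblems are
coupled through the triangle term, so the Jacobi sweep is only
approximately coordinate-optimal; the trace is recorded for inspection.

## From W* to complexes

An interaction {i, j} *qualifies* when rule(w_ij, w_ji) ≥ w_min; the rule is
`max` by default (co-clustering likelihood is conceptually symmetric, so
the larger oriented entry is taken as the pair's score), with `min` and
`mean` available for sensitivity analysis. A depth-first search seeded at
every protein collects its base cluster; after deduplication these are the
connected components of the qualified-edge graph. Base clusters smaller
than `min_size` (default 2 — a complex needs at least two interacting
proteins) are dropped.

Base clusters with overlap score |BC_p ∩ BC_q| / |BC_p ∪ BC_q| ≥ os_max are
then merged single-link style: connected components of the ≥-threshold
meta-graph are replaced by the union of their members, without rescoring
against merged unions — the unique order-independent reading of single-link
merging. Output order is canonicalized (sorted member tuples) so results
are reproducible byte for byte. Raising w_min refines base clusters;
raising os_max makes merging more restrictive; both thresholds are
conventionally tuned on a 0–1 grid with step 0.1.

## Evaluation protocol

A prediction *matches* a reference complex when the neighborhood-affinity
matching rate |A∩B|²/(|A||B|) is ≥ 0.2 (plain Jaccard selectable).
Precision = TP/(TP+FP) over predictions; recall counts matched *reference*
complexes over all references, so recall stays ≤ 1 when several predictions
hit one reference; f is their harmonic mean (0 when both are 0). Empty
prediction sets report precision 0 with a flag. Accuracy is
√(Sn·PPV) from the reference × prediction overlap table t_ij:
Sn = Σ_i max_j t_ij / Σ_i |ref_i|, PPV = Σ_j max_i t_ij / Σ_ij t_ij. MMR is
the total weight of a maximum one-to-one reference–prediction matching
(solved by linear assignment; only the optimal value matters, ties among
matchings are irrelevant) divided by the reference count. Note Acc = 1 on a
self-comparison only for *disjoint* families: overlapping complexes
inflate the PPV denominator, so a catalog with shared proteins scores
Acc < 1 against itself by construction. Diagnostics include the fraction
of predicted cluster pairs sharing ≥ 1 protein and the number of distinct
proteins covered.

## Synthetic benchmark

The generator plants complexes of configurable sizes (optionally sharing
proteins) on a background, draws within-complex edges with probability
p_in and all other edges with p_out, and gives each complex a block of
coherent terms in its preferred aspect subset only; every protein also
receives `noise_terms` random terms per aspect from a large disjoint pool.
Defaults — five complexes of eight proteins, one pair sharing two, p_in =
0.9, p_out = 0.02, 30 background proteins, three coherent terms per
preferred aspect, one noise term — are the study conditions used
throughout the tests and the acceptance script (n_V = 68; sizes chosen so
the whole pipeline runs in seconds on one core). Coherent term blocks are
disjoint across complexes and aspects so preference recovery is
unambiguous; shared proteins inherit the union of their complexes' terms
and preferred aspects.

What this emulates — and what it does not: planted instances have sharp
density contrast and block-constant functional similarity, no scale-free
degree structure, no GO-DAG term correlations, and no annotation bias
toward well-studied proteins. Passing the recovery tests therefore shows
the estimator does what it is designed to do under its own assumptions; it
does not certify performance on real interactome data, where edge noise
and annotation incompleteness are far less benign.

A fixed 12-protein worked instance (two complexes of six sharing two
proteins, preferring {p, c} and {f}) is bundled for documentation and
tests. Because its two planted complexes are connected through their shared
proteins, any w_min that keeps within-complex edges qualified yields their
union as one base cluster — the expected single-link behavior, still a
threshold-0.2 match to both references.

## Numerical choices and limitations

* All matrices are dense NumPy arrays; the triangle term Σ_k w_ik w_jk t_ik
  t_jk is computed as (W∘T)(W∘T)ᵀ, identical to a common-neighbor sweep but
  BLAS-backed. Dense storage is the right regime for the hundreds-of-protein
  instances this package targets; very large interactomes would need a
  sparse refactor.
* Feasibility (W ∈ [0,1], rows of R on the simplex to 1e−9) is an invariant
  asserted after every update in the test suite, not an emergent property.
* Determinism: one seeded `numpy.random.Generator` per run; fixed seeds
  give bit-identical matrices, traces and output files.
* The grid tie-break in the acceptance script ranks cells by f-measure,
  then accuracy, then MMR: at small w_min a single giant cluster can clear
  the 0.2 affinity threshold against every reference and tie the best
  f-measure, and the secondary keys select the representative solution
  instead.
* No functional-enrichment testing (requires the GO DAG and background
  sets), no identifier mapping, no weighting of the objective's two
  evidence terms, and no parallel execution.
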