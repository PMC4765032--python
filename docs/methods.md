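# Methods

## Model

`cofuse` treats protein complex detection as the recovery of a soft
membership matrix from an integrated co-complex similarity network. The
pipeline has two integration layers followed by a decomposition:

**Consensus matrices.** For each data source, n_p base clustering results
are collapsed into C_ij = (#results co-clustering i and j) / n_p. A pair
that shares several clusters within one result counts once for that
result: the ensemble estimate is over *results*, not clusters. Proteins
assigned to no cluster in any result, or outside the source's coverage,
get all-zero rows and columns, so absence of evidence is not confused
with evidence of absence. Consensus matrices are built independently per
source because sources differ in coverage and noise.

**Affinity refinement.** Raw TAP-derived affinity scores (consumed as a
precomputed edge list; computing them from purification records is out of
scope) are mapped through C = 1 − exp(−s) for s > 0, else 0. The map is
monotone, bounded in [0, 1), and zero exactly on (−∞, 0]; negative raw
scores indicate pairs unlikely to be co-complexed and are discarded.

**Similarity network fusion.** The M matrices are fused by cross
diffusion. Each matrix yields a full kernel A (off-diagonal rows rescaled
to sum 1/2, diagonal pinned at 1/2 — row-stochastic and independent of
self-similarity scale) and a local kernel B over each protein's L most
similar positive neighbours (row-normalized; ties at the L-th rank break
toward the smaller protein index for determinism). Status matrices start
at A and iterate

    W⁽ᵐ⁾ ← B⁽ᵐ⁾ · mean_{v≠m} W⁽ᵛ⁾ · B⁽ᵐ⁾ᵀ,

followed by full-kernel renormalization and symmetrization each sweep.
Similarity supported by trusted neighbourhoods in one view thus
propagates through the others, while the kernel normalization keeps the
process scale-free. Iteration stops when the largest entrywise change
falls below `snf_tol` or after `snf_max_iter` sweeps; the fused result is
the average of the status matrices, symmetrized, diagonal zeroed before
decomposition (self-similarity carries no co-complex information
downstream). All-zero rows (isolated proteins) keep A_ii = 1 and an empty
B row, so they pass through fusion isolated rather than causing division
by zero.

**Decomposition.** Memberships θ (N×K, rows on the probability simplex)
define the doubly stochastic reconstruction Ŵ_ij = Σ_k θ_ik θ_jk / s_k,
s_k = Σ_z θ_zk, interpreted as a two-step random walk from protein to
protein via complexes under a uniform protein prior. The objective is
generalized KL divergence plus a graph-Laplacian penalty weighted by λ
that pushes strongly connected proteins toward similar membership rows.
Since both terms are linear in the scale of W, λ's effect depends only on
the structure of W, not its magnitude.

**Discretization.** Per protein, memberships are sorted descending and
the protein joins all complexes ranked above the largest consecutive gap
(the smallest rank wins ties, so an uninformative uniform row yields a
single assignment). This naturally produces overlapping complexes.
Columns with no members vanish; complexes below `min_size` (default 3)
are dropped, matching standard practice in complex prediction.

**Metrics.** Sn, PPV and Accuracy = √(Sn·PPV) use the overlap-count
matrix T_ij = |x_i ∩ y_j|; PPV's denominator counts only predicted
members that occur in some benchmark complex, so predictions disjoint
from the benchmark are neutral rather than penalized. FRAC counts
benchmark complexes matched by at least one prediction at overlap score
|x∩y|²/(|x||y|) ≥ ω. Matching is many-to-many. Benchmarks are first
restricted to the input's protein universe with sub-minimum complexes
dropped, to avoid penalizing predictions for unobservable proteins.

## Solver

The objective is non-convex; the solver uses multiplicative updates with
the gradient split ∇J = ∇⁺ − ∇⁻, where ∇⁻ = 2Zθ/s + 2λWθ (Z = W ⊘ Ŵ on
the support of W) and ∇⁺ = q/s² + 1 + 2λDθ (q_k = θ_kᵀZθ_k). The update

    θ_ik ← θ_ik (∇⁻_ik + Σ_l θ_il ∇⁺_il) / (∇⁺_ik + Σ_l θ_il ∇⁻_il)

carries the simplex multiplier in its row terms and is followed by exact
row renormalization. A backtracking safeguard then interpolates between
the current and proposed iterates (a convex combination, so feasibility
is exact) until the objective does not increase beyond 1e−12 relative;
if no step length helps, the solver declares convergence. The recorded
objective trace is therefore non-increasing to numerical slack by
construction. Each iteration costs O(nnz(W)·K + N·K): Z is evaluated
only on W's sparsity pattern and W is never densified.

Numerical conventions: 0·log 0 = 0; a pair with W_ij > 0 but Ŵ_ij = 0
gives an infinite objective, unreachable from the strictly positive
uniform(0,1) row-normalized initialization because multiplicative updates
preserve support. Columns whose mass falls below 1e−12 contribute nothing
to Ŵ and are dropped at discretization. Convergence is declared when the
relative objective decrease over a 10-iteration window falls below
`dsmd_tol` (default 1e−9), with `dsmd_max_iter` = 200 as the cap. Fits
are deterministic given the seed. With K = 1 the simplex admits a single
feasible point and the gap rule is undefined; every protein joins the one
complex.

## Defaults

| parameter | default | meaning |
|---|---|---|
| K | 2000 | complex-count upper bound for genome-scale input; surplus columns empty out and are dropped. Scale to ~3× the expected complex count on small problems |
| λ | 32 | Laplacian weight; see scaling note below |
| L | 20 | fusion neighbourhood size |
| snf_max_iter / snf_tol | 20 / 1e−6 | fusion stopping rule |
| dsmd_max_iter / dsmd_tol | 200 / 1e−9 | solver stopping rule |
| ω | 0.2 | overlap-score match threshold |
| min_size | 3 | smallest reported complex |

## Synthetic data

The generator plants `n_complexes` complexes with sizes uniform on
[size_min, size_max]; a requested fraction of assigned proteins belongs
to two complexes (raised to the minimum feasible overlap when the drawn
sizes exceed N, logged), and leftover proteins are background. Noisy
base clusterings start from the truth and drop each member with
probability `drop_rate`, split clusters with probability `split_rate`,
and merge adjacent clusters with probability `merge_rate`. Affinity
tables score within-complex pairs uniform on [p_within − 0.1, p_within]
and spurious pairs (present with probability `noise`) on (0, noise]. All
randomness flows from explicit seeds.

What this emulates — and does not. The perturbations mimic the gross
error modes of real base methods (missed members, fragmentation, merged
neighbours) and the affinity model mimics a scored TAP screen with a
clear within/between margin. Real data differ in ways the generator does
not model: complex sizes are heavy-tailed down to pairs, affinity noise
is correlated with protein abundance, base methods make correlated (not
independent) errors, and most of the proteome belongs to no annotated
complex. Passing tests on these fixtures therefore demonstrate the
correctness and the qualitative behaviour of the machinery, not expected
performance on any particular organism's data.

## The useful range of λ scales with problem size

The KL term's preference for block structure grows like ΣW·log(N/s̄) (s̄
the typical complex size), while the Laplacian cost of a block-structured
θ grows like λ times the fused matrix's between-block mass. Both are
linear in the scale of W, so the crossover λ depends on the log-resolution
and on how clean fusion leaves the network. At genome scale
(N in the thousands, log(N/s̄) ≈ 7) λ = 2^5 sits in the regime where the
penalty prunes irrelevant membership columns while the KL term still
pins the blocks. On desk-scale problems (N ≈ 200, log(N/s̄) ≈ 2.3, and a
fusion neighbourhood L = 20 comparable to the complex size, which leaves
~30% of the fused mass between blocks) the same λ = 2^5 crosses into
over-smoothing: the optimum genuinely favours blended memberships, and
accuracy at λ = 2^5 falls below accuracy at small λ. This is a property
of the objective at that size, not of the optimizer — warm-starting from
the planted solution descends to the same smoothed optimum. Users
applying the model to small networks should scale λ down by roughly the
ratio of log(N/s̄) to its genome-scale value; the package's own
small-problem examples use λ ≈ 2.

## Known limitations

- Fusion with L greater than the typical complex size admits noise
  neighbours into the local kernels and the diffusion equilibrium mixes
  a material fraction of mass between complexes; on small inputs this
  also narrows the gap between fusion and plain matrix averaging.
- The solver finds local minima; different seeds give different (all
  feasible, all monotone) fits. K well above the true complex count with
  small λ yields duplicate near-copies of complexes rather than empty
  columns.
- The evaluation suite implements the Accuracy/FRAC family only;
  complex-level specificity and f-measure variants are out of scope.
- Raw affinity scoring from purification records, GO/expression-based
  evidence, and supervised source weighting are out of scope by design.
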