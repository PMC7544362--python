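# Methods

## Model

`dircp` works with directed, unweighted graphs on `n` nodes encoded as a
binary adjacency matrix `A` (`A[u, v] = 1` iff `u → v`); self-loops are
allowed, multi-edges are not; `m = Σ A` counts a reciprocated pair twice.

The target meso-scale structure partitions nodes into four sets in the fixed
order `(Pout, Cin, Cout, Pin)`.  The idealized pattern is the 4×4 block
indicator `M` with ones on exactly five blocks — Pout→Cin, Cin→Cin,
Cout→Cin, Cout→Cout, Cout→Pin — which drawn as a matrix traces an "L".
The number of ordered node pairs lying on the "L" for set sizes
`(a, b, c, d)` is `a·b + b² + c·b + c² + c·d`, self-pairs included.

The generative model **DCP(p₁, p₂)** is a stochastic block model: every
ordered pair (diagonal included) independently carries an edge with
probability p₁ if the pair is on the "L" and p₂ otherwise, with
`0 ≤ p₂ < p₁ ≤ 1`.  `DCP(1, 0)` is the idealized structure; the
one-parameter family `DCP(½+p, ½−p)`, `p ∈ (0, 0.5]`, varies only the
signal–noise contrast and is the basis of all benchmarks.  Sampled graphs
order their nodes block-contiguously so adjacency heat maps render the "L"
directly.

Self-pairs are included in sampling, pair counts, the likelihood and DCPM
throughout: the model explicitly permits self-loops and the quality measures
sum over all ordered pairs, so excluding the diagonal would silently change
every density denominator (`n²` rather than `n(n−1)`).

## Profile likelihood

For a hard partition `g`, let `E1`/`N1` be the edge/pair counts on "L"
blocks and `E2`/`N2` the off-"L" counterparts.  The two density parameters
profile out analytically (`p̂₁ = E1/N1`, `p̂₂ = E2/N2`) leaving

```
ℓ(g) = E1·log p̂₁ + (N1−E1)·log(1−p̂₁) + E2·log p̂₂ + (N2−E2)·log(1−p̂₂) ≤ 0
```

with the convention `0·log 0 = 0` (via `scipy.special.xlogy`), so degenerate
densities — including the perfect structure, where `ℓ = 0` — stay finite.
Empty pair classes give `p̂ = 0` and contribute nothing.  This function is
both the MaxLike objective and the criterion by which every detector names
its anonymous clusters.

## Detectors

All four detectors share the final two stages: **k-means++** (scikit-learn,
k = 4, `n_init = 10`, tolerance 1e-6, max 300 Lloyd iterations, seeded) on a
per-node score matrix, then an exhaustive search over all injective maps
from occupied clusters into the four set names (≤ 24 candidates), keeping
the map with the largest profile likelihood.  Exact ties are broken by the
lexicographically smallest map in block order, which makes the output
deterministic and invariant to cluster renaming.  Fewer than four occupied
clusters (coincident score rows, degenerate graphs) are handled by the same
enumeration over partial injections.

**hits.** Authority and hub scores are the principal right/left singular
vectors of `A` with non-negative entries and unit Euclidean norm, computed
by deterministic power iteration on `AᵀA` starting from the all-ones vector
(tolerance 1e-13 on the iterate, cap 10 000 iterations).  The start vector
can never be orthogonal to the Perron eigenspace of the non-negative
operator, and on a degenerate leading eigenspace (e.g. a 2-cycle) the
iteration converges to the deterministic projection of the start vector,
so results are reproducible without a random eigensolver state.  The n×4
score matrix has columns `Pout = max(a)−a`, `Cin = a`, `Cout = h`,
`Pin = max(h)−h`, then rows are rescaled to unit Euclidean norm.  Assigning
authority to core-in and hub to core-out matches the structural roles (Cin
receives, Cout sends); the opposite convention is a column permutation of
the row-normalized matrix — an isometry of the row geometry — and provably
yields the same final partition (covered by a test).

**advhits.** One affinity score per node per set, propagated with the
reward–penalty matrix `D = 2M − 1` (+1 where an edge matches the "L", −1
otherwise).  With `w₁ = 1 − m/n²` and `w₂ = m/n²`, the raw update for set
`i` scores present out-edges (`w₁`, against row `eᵢ` of `D`), missing
out-edges (`−w₂`), present in-edges (`w₁`, against column `dᵢ`) and missing
in-edges (`−w₂`); the all-ones matrix implicit in the missing-edge terms
includes the diagonal.  After each column update the whole matrix is
renormalized row-wise onto the simplex (subtract the row minimum, divide by
the shifted sum; rows whose shifted sum is below 1e-10 become uniform ¼).
Columns are updated Gauss–Seidel style in block order; iteration stops when
the largest entrywise change of the normalized matrix within an outer
iteration drops below 1e-8, with a cap of 1000 synchronous iterations.  If
the synchronous scheme has not converged, an asynchronous fallback updates
one node's four scores (renormalizing that row) at a time in index order,
capped at the same number of sweeps, after which clustering proceeds
regardless — termination is forced.  Raw scores are initialized i.i.d.
uniform(0, 1) from the seed.

**maxlike.** Kernighan–Lin ascent on the profile likelihood.  One sweep
moves every node exactly once: at each step the single best
(node, new-set) move over still-unlocked nodes is applied — even when its
likelihood change is negative — and the node is locked; the best state
encountered during the sweep (its start included) is returned.  Sweeps
repeat until one fails to improve by more than 1e-10.  The whole search runs
from 11 independent uniform-random label initializations by default (the
number of runs used per method in the reference comparisons) and returns the
best restart.  Equal-value moves prefer the lowest node index, then block
order; empty sets are permitted during the search, since the likelihood is
well defined there and forbidding them can trap the ascent.  Move evaluation
is O(1) via cached per-node block edge counts (`ko`, `kin`, self-loops
tracked separately) plus a closed-form update of the "L" pair count; each
sweep step evaluates all n×4 moves with vectorized `xlogy` arithmetic.

**degree.** k-means++ directly on the raw two-column
(in-degree, out-degree) matrix — deliberately unstandardized, as the
baseline is defined on the degrees alone — then the shared cluster naming.

## Quality measures and significance

**DCPM** (directed core–periphery modularity):
`DCPM(g) = (1/m) Σ_{u,v} (A_uv − m/n²) M_{g_u g_v}` over all ordered pairs,
diagonal included.  It lies in (−1, 1), is exactly 0 when all nodes share
one set, equals `1 − m/n²` for the perfect "L" and `−(#L-pairs)/n²` for its
complement.  It is undefined (an error) on an edgeless graph.

**L-statistic**: `E1/N1 − E2/N2`, the within-"L" edge density minus the
off-"L" density, in [−1, 1].  Partitions for which one pair class is empty
raise an error rather than silently reporting 0.

**Monte Carlo test.** The observed statistic is the L-statistic of the
partition the chosen detector finds on the input graph.  Each of R
replicates draws a null graph, re-runs the *same detector* on it and records
its L-statistic; re-detection (rather than re-scoring a fixed partition) is
what makes the p-value detector-specific.  The p-value is the exact Monte
Carlo form `(1 + #{null ≥ observed}) / (1 + R)` with floor `1/(R+1)`.  Two
null models: a directed Erdős–Rényi graph without self-loops carrying
*exactly* the observed number of edges (uniform placement without
replacement; matching m exactly rather than in expectation minimizes null
variance and is immaterial at benchmark sizes), and a configuration model
realized by `10·m` attempted directed double-edge swaps
`(a→b, c→d) ⇒ (a→d, c→b)`, rejecting swaps that would create self-loops or
duplicate edges, which preserves both degree sequences exactly while
guaranteeing a simple digraph.  A replicate whose detection or statistic
fails is resampled once and then scored conservatively as −1.

## Benchmarks and the synthetic generator as study conditions

The synthetic experiments mirror the reference study conditions: four sets
of 100 nodes (n = 400) unless stated.

* **Benchmark 1** sweeps `p` in `DCP(½+p, ½−p)` and records, per sampled
  network and detector, the adjusted Rand index (ARI, scikit-learn's
  permutation-model implementation) against the planted partition and the
  DCPM of the detected partition.
* **Benchmark 2** sweeps `p₁` and the noise ratio `p₂/p₁ ∈ [0, 1)`
  (default grids: p₁ from 0.025 to 1.0 in steps of 0.025; ratio from 0 to
  0.95 in steps of 0.05 — exposed as parameters rather than hard-coded).
* **Benchmark 3** fixes `p = 0.1` and scales one set's size by
  `2^k, k ∈ {−3..3}` while the other three stay at the base size.
* **Quality validation** samples 20 networks at each of
  `p ∈ {0.1, 0.04, 0.02}` — detectable, marginal, and (mostly) undetectable
  regimes — runs Hits, AdvHits and MaxLike on each, and summarizes with
  Kendall τ (tie-corrected τ-b, scipy) between DCPM, ARI and the Monte
  Carlo p-values.  The headline τ(DCPM, ARI) is computed over all
  (network, method) rows without p-value filtering; a p < 0.05-filtered
  variant is also reported when p-value columns are present.  Monte Carlo
  p-values use 250 replicates by default; they can be skipped
  (`null_replicates=None`) when only the DCPM/ARI relationship is studied.

Per-cell seeds are derived from a master seed by hashing the parameter tuple
(CRC-32 into a `SeedSequence`), so tables are bit-identical across runs and
cells are independent and embarrassingly parallel.

The generator emulates exactly the block-independent Bernoulli world of the
DCP model.  Real networks deviate from it in ways the model ignores — heavy-
tailed degrees inside blocks, reciprocity, transitivity, overlapping or
outlier nodes — so passing benchmarks demonstrates correctness of the
machinery and recovery under the model's own assumptions, not performance
guarantees on empirical data.  The configuration-model null exists precisely
because the ER null is blind to degree heterogeneity.

## Numerical choices and defaults

| quantity | default | note |
|---|---|---|
| k-means++ restarts `n_init` | 10 | best of 10 by within-cluster SS |
| k-means tolerance / max iters | 1e-6 / 300 | scikit-learn Lloyd |
| AdvHits tolerance / cap | 1e-8 / 1000 | per outer iteration, max entrywise change |
| AdvHits uniform-row epsilon | 1e-10 | shifted row sum below this ⇒ ¼ each |
| MaxLike restarts | 11 | uniform-random initial labels |
| MaxLike sweep improvement tol | 1e-10 | stop when a sweep gains less |
| HITS power-iteration tol / cap | 1e-13 / 10 000 | all-ones start vector |
| Monte Carlo replicates | 250 | p-value floor 1/(R+1) |
| config-model swap factor | 10 | attempted swaps per edge |

Whether AdvHits renormalizes after each column or after a full pass is a
genuine design fork; this implementation renormalizes after each column
(Gauss–Seidel), the literal reading of the stepwise procedure.  Restarts in
MaxLike use uniform-random initializations only (no structured, e.g.
degree-based, starts).

## Acceptance script problem sizes

`scripts/acceptance.py` averages MaxLike ARI over 12 network samples per
signal level (the reference tables average over 50) and runs the
quality-validation grid at its reference size of 20 networks per signal
level without Monte Carlo p-values.  These sizes keep the script in the
minutes range on one CPU while holding Monte Carlo standard errors of the
reported means well inside the comparison tolerances.

## Known limitations

* Dense-matrix representation throughout: memory is O(n²); the toolkit is
  desk-scale (thousands of nodes), not web-scale.
* The cluster-naming step maximizes homogeneity but does not penalize a
  sparse "L": on structureless inputs the highest-likelihood labeling can
  have low density inside the "L" and DCPM near or below zero — inspect
  partitions before discarding them, and rely on the Monte Carlo test.
* Exactly four sets; no outlier set, no soft membership, no weighted edges,
  and no alternative directed block patterns (e.g. bow-tie).
* AdvHits convergence is empirical, not guaranteed; the asynchronous
  fallback and hard caps force termination in all cases.
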