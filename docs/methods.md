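# Methods

## Model and scope

`sirthresh` studies discrete-time SIR dynamics on simple undirected graphs.
Each time step, synchronously, every infected node transmits to each
susceptible neighbor independently with probability β and then recovers with
probability γ; nodes infected at step t become infectious at step t+1; the
process absorbs when no infected nodes remain.  The observable is the final
recovered fraction r, and the control parameter is the effective spreading
rate λ = β/γ.  All thresholds are quoted in λ with the γ = 1 convention; for
γ < 1 the same reciprocal formulas are applied to λ, which is exact for the
MFL expression and conventional for the spectral ones.

### Micro-order of updates

Synchronous updating leaves one choice open: whether an infected node can
transmit in the step it recovers.  The default (`transmit_first=True`) lets
it — transmission is evaluated from the current infected set, then
recoveries are applied.  This is the standard convention and the only one
with sensible behavior at γ = 1: the alternative order
(`transmit_first=False`, provided to probe sensitivity) recovers every node
before it ever transmits when γ = 1, so nothing spreads.  Newly infected
nodes never recover in the step they are infected in either order.

## Threshold predictors

* MFL: λ_c = ⟨k⟩/(⟨k²⟩ − ⟨k⟩), undefined when ⟨k²⟩ ≤ ⟨k⟩ (no excess
  degree, e.g. a single edge).
* QMF: λ_c = 1/Λ_A.  Λ_A is computed by dense `eigh` for N ≤ 300 and by
  ARPACK (Lanczos, tolerance 1e−10, max 10⁴ iterations, deterministic
  all-ones start vector) above.
* DMP: λ_c = 1/Λ_M.  Λ_M is the leading eigenvalue of the 2N×2N block
  companion matrix [[A, I−D],[I, 0]], kept sparse and solved by ARPACK
  (Arnoldi, same tolerances).  On trees the non-backtracking spectrum is
  trivial and a `NoCycleError` routes callers to the undefined-threshold
  path.  When Λ_M ≤ 1 the predicted λ_c ≥ 1 is unreachable with β ≤ 1 and
  the value is flagged.

### Numerical choices for the non-backtracking solve

The block matrix is non-symmetric and, on periodic graphs (cycles, bipartite
graphs), several eigenvalues share the spectral circle; the Perron root can
even be numerically defective (a double root that splits as 1 ± ε with
ε ~ √machine-eps).  Three safeguards follow:

1. graphs with 2N ≤ 600 are solved densely, where the whole spectrum is
   available;
2. the reported eigenvalue is the spectral radius max|κ|, which is
   second-order accurate under the defective-root split, and a numerically
   real positive eigenvalue must exist on the circle (tolerance 1e−6) or the
   solve errors out rather than silently truncating;
3. the sparse path asks for the dominant eigenvalue alone and widens the
   Krylov subspace (k = 6, ncv = 40) only if that fails to yield a real
   positive root.

The node-space non-backtracking centrality is the first N components of the
2N eigenvector, nonnegative and unit-normalized; IPR values quoted for "the
non-backtracking matrix" refer to this node-space vector.  The explicit
2E×2E directed-edge matrix (entry 1 for edge pairs (i→j),(j→l) with l ≠ i)
is implemented as a dense validation oracle, capped at 2000 edges, and the
test-suite requires block/edge agreement to 1e−8 on every cyclic fixture and
on random configuration networks.

## Numerical threshold: the relative variance

For each λ on a grid an independent final-size ensemble is generated and

    χ = (⟨r²⟩ − ⟨r⟩²) / ⟨r⟩²

is evaluated; the numerical threshold is the λ at the global χ maximum (ties
→ smallest λ; an argmax on a grid endpoint raises a boundary flag that the
sweep window was too narrow).  No smoothing is applied — the raw-grid argmax
keeps the estimator auditable.

The relative-variance normalization was chosen against the
susceptibility-style alternative N·(⟨r²⟩ − ⟨r⟩²)/⟨r⟩ (also provided, with an
unscaled variant) on evidence: on a 6-regular random graph with N = 5000 and
γ = 1, where the exact threshold is 1/(k−1) = 0.2, the relative variance
peaks at the grid point nearest 0.2 while the susceptibility form peaks near
0.25, because the absolute variance keeps growing through the bimodal regime
above the transition while the squared mean in the denominator of χ
suppresses it.  The two susceptibility variants differ only by the constant
N and share their argmax exactly (unit-tested).

The default sweep grid is geometric with 25 points over
[0.25, 4]×λ_c^MFL, clipped to λ ≤ 1/γ — centered where theory predicts the
transition.  Note the grid's multiplicative resolution (~12% between
neighbors) bounds the precision of any single threshold estimate; λ_c^MFL
itself is always a grid point, so an estimate exactly equal to the MFL
prediction means "within one grid step of it".

Default ensemble sizes are 10⁴ realizations for standalone ensembles and
2000 per grid point in the sweeps; the package's own validation experiments
(threshold recovery on 6-regular graphs at N = 5000; size scaling at
N = 10³–10⁴) use 2000 per point, which resolves the peak position to one
grid step while keeping a full pipeline run in minutes on one CPU.  Users
reproducing published-quality curves on larger networks should raise this
to ≥10⁵.

## Synthetic networks

The generator emulates uncorrelated scale-free configuration networks:
degrees i.i.d. from P(k) ∝ k^(−ν_D) on [k_min, k_max] with k_min = 3 and
the structural cutoff k_max = ⌊√N⌋ by default (an odd degree sum is
repaired by redrawing one uniformly chosen entry), wired by uniform stub
matching.  Self-loops are removed and multi-edges collapsed rather than
rejection-sampled; the removed-edge counts are reported, and the resulting
degree-sequence bias is O(1) edges at the structural cutoff.  Measured
assortativity satisfies |r| < 0.05 for N ≥ 10⁴, the "uncorrelated" regime in
which MFL ≡ DMP degeneracy is asserted.

Degree-degree correlations are tuned by greedy degree-preserving double-edge
swaps: since degrees are fixed, Pearson's r is affine in the edge
cross-product sum Σ d_u d_v, so a proposed swap is accepted iff it moves
that sum toward the target (tolerance 0.01 on r, proposals uniform over edge
pairs, simplicity preserved).  Unreachable targets return the best-effort
graph with a warning.  On regular graphs r is undefined (zero endpoint
degree variance) and the operation refuses to run.

What the generator does *not* emulate: clustering, community structure,
degree correlations beyond the Pearson coefficient, weights, direction, and
temporal structure.  Passing tests on these synthetic ensembles therefore
validates the pipeline's correctness and the uncorrelated-network theory; it
does not by itself certify predictor rankings on real-world networks, which
is precisely why the structural covariates (r, c, Q, k-core, IPR) are
computed and reported per network.

## Structural covariates

* Assortativity: Newman's Pearson estimator over oriented edge-endpoint
  pairs (each edge counted in both orientations); flagged undefined rather
  than NaN on zero variance.
* Clustering c: mean local (Watts–Strogatz) coefficient with degree-<2
  nodes contributing 0 — the conventional definition for the c = 0.1
  stratification boundary; global transitivity is recorded alongside for
  diagnostics.
* Modularity Q: Newman–Girvan modularity of the partition found by the
  deterministic greedy (Clauset–Newman–Moore) agglomeration; the algorithm
  name and seed are recorded with the value, since Q is
  partition-dependent and reproducibility was preferred over optimality.
* k-core index: iterative degree pruning.

## Comparison conventions

Errors per method u ∈ {MFL, QMF, DMP}: abs_err = |λ_c^u − λ_c|,
rel_err = abs_err/λ_c.  The "closest method" minimizes the absolute error;
since λ_c > 0 is shared within a network, absolute and relative error induce
the same winner (unit-tested).  Exact ties resolve lexicographically
DMP < MFL < QMF and are flagged.  Records with undefined DMP (trees) are
excluded from the closest-method competition rather than imputed; records
with undefined r are excluded from r-binned curves with a logged count.
Binned error curves average rel_err in windows (x − Δx/2, x + Δx/2) with
Δx = 0.1 by default, centers anchored on multiples of Δx; empty bins are
reported empty (NaN), never as zero.

## Localization classes

A network is hub-localized (LHN) when Λ_A is strictly closer to √k_max than
to ⟨k²⟩/⟨k⟩, and k-core-localized (LKN) otherwise; exact ties go to LKN
with a flag (arbitrary but fixed).  IPR = Σ vᵢ⁴ of the unit-normalized
principal eigenvector, bounded in [1/N, 1].

## Known limitations

* Asynchronous (Gillespie) dynamics, SIS dynamics, and weighted/directed/
  temporal networks are out of scope.
* The χ-peak threshold inherits the sweep grid's resolution; refine the grid
  near the peak for sharper estimates.
* Greedy assortativity rewiring can stall short of extreme targets
  (|r| ≳ 0.3 on heavy-tailed graphs) because hub–hub edge slots saturate;
  the warning flag reports this honestly.
* The DMP threshold is a spectral condition only; full message-passing time
  integration is not implemented.
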