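# Methods

## Model

Expression profiles X¹, …, Xⁿ ∈ ℝᵖ are modeled as i.i.d. draws from
N(0, Σ) with positive-definite Σ and precision matrix Ω = Σ⁻¹. The
network of interest is the conditional-independence graph
E = {(i, j) : ω_ij ≠ 0}. Under normality each gene satisfies the
self-regression X_i = Σ_{j≠i} β_ij X_j + ε_i with
β_ij = ρ^{ij} √(ω_jj/ω_ii), where ρ^{ij} is the partial correlation of
genes i and j given all others, so estimating the sparse vector of
partial correlations recovers the graph.

The hub-aware estimator minimizes the joint penalized squared error

    ½ Σ_i w_i ‖X_i − Σ_{j≠i} ρ^{ij} √(ω_jj/ω_ii) X_j‖²
      + αλ Σ_{hub-adjacent i<j} |ρ^{ij}| + λ Σ_{non-hub i<j} |ρ^{ij}|,

with the loss weights w_i fixed at one (the vector is accepted and
honored, but no weighting scheme is provided). α ∈ (0, 1] scales down
the penalty on pairs touching a previously known hub; α = 1 or an empty
hub set gives the plain estimator, and this reduction is exact — the
two code paths produce bit-identical output, which the tests assert.

The likelihood variant maximizes log|Ω| − tr(SΩ) − Σ P_ij |ω_ij| with
the same hub-adjacency penalty pattern P, where S is the
maximum-likelihood sample covariance (divisor n).

## Pairwise solver

The solver is an active-shooting coordinate descent on an (unmaterialized)
stacked regression: each pair's gradient and curvature reduce to O(n)
inner products, and residual vectors are maintained incrementally
(adding back the old contribution of a coordinate and subtracting the
new one) rather than recomputed; agreement with full recomputation is
tested to 1e−10. The schedule is:

1. initialize all ω_ii = 1;
2. initialize every ρ^{ij} by marginal soft-thresholding (threshold
   αλ or λ, divided by the pair's curvature);
3. cycle over the active (nonzero) coordinates until the largest change
   is below τ, dropping a coordinate the moment it hits exactly zero;
4. run one full sweep over all pairs; return to 3 unless the sweep's
   largest change is below τ;
5. update each 1/ω_ii to the mean squared residual of gene i's
   regression, using the previous round's ω values on the right-hand
   side (Jacobi update — the literature leaves Jacobi-vs-Gauss–Seidel
   open, and the deferred form is what the update formula literally
   states);
6. repeat from 2 until the ω diagonal stabilizes.

Convergence of the ρ stage additionally requires the exact subgradient
(KKT) residual — computed vectorized from the full residual matrix — to
fall below 10τ; a small-coordinate-change test alone does not bound the
gradient, so the sweep loop keeps refining (tightening its internal
tolerance geometrically) until the certificate holds. Every solution
returned with `converged=True` therefore carries a verified optimality
certificate at its reported ω.

### The ω fixed point

The ω update defines a fixed-point map whose plain iteration contracts
slowly (rates around 0.75–0.8 on realistic hub-network instances) and,
in the strongly overfit regime (λ far below the selection scale, p ≈ n,
hundreds of active coordinates), can enter an exact 2-cycle with no
attracting fixed point. The package therefore solves the fixed point by
Steffensen-accelerated iteration: two plain rounds give a secant
estimate r of the contraction rate, and the iterate is extrapolated by
δ·r/(1−r) (negative r damps oscillation). The accelerated iteration
targets the same fixed point and typically converges within about ten ω
rounds at the default tolerances; a run that stops improving for six
rounds is declared non-convergent, returned with `converged=False` and
a warning, and excluded from model selection. Intermediate ω rounds
solve the ρ stage at a relaxed tolerance (they only steer the fixed
point); convergence is only ever declared from a full-tolerance solve,
so reported solutions are unaffected.

Defaults: τ = 1e−6; ω tolerance τ (relative); caps of 1000 active
cycles, 100 sweeps, 20 ω rounds. λ = 0 is accepted only when n > p;
zero-variance genes are rejected at preprocessing. Pairs are ordered
row-major along the upper triangle, fixed so that output files are
byte-reproducible.

## Likelihood solver

The penalty-matrix graphical lasso follows the classical block
coordinate scheme: W estimates Σ with diagonal fixed at s_ii + λ (the
diagonal thus carries penalty λ, matching the closed form
ω̂_ii = 1/(s_ii + λ) for diagonal S and keeping W positive definite —
whether the original experiments penalized diagonals is not stated, and
this choice matches the algorithm they delegate to); each column's
off-diagonal block solves a lasso subproblem with per-coordinate
thresholds P_·j by cyclic coordinate descent at tolerance tol/10;
cycling stops when the largest change in W over a full pass is below
tol (default 1e−4 · mean |diag S|). Ω is recovered per column via
ω_jj = 1/(w_jj − w₁₂ᵀβ), ω_·j = −β ω_jj, symmetrized by averaging, and
checked positive definite; the reported covariance factor is Ω⁻¹, so
the pair is consistent to machine precision. The penalized
log-likelihood is recorded after every sweep and is non-decreasing
(tested).

## Tuning-parameter selection

GIC(λ, α) = Σ_i { n·log RSS_i + log(log n)·log(p−1)·df_i }, where
RSS_i is gene i's residual sum of squares at the fitted (ρ̂, ω̂) and
df_i counts its selected neighbors — each edge is counted at both of
its endpoints, as the criterion is written. The default grid is 20
log-spaced λ values from λ_max (the smallest λ whose marginal
initialization is empty at α = 1) down to 0.05·λ_max, crossed with
α ∈ {0.5, 0.6, …, 1.0}; the argmin is taken over converged fits, with
ties broken toward larger λ then larger α (the sparser, less-relaxed
model). λ is swept descending with the ω diagonal warm-started from the
previous fit; since the ρ stage is re-initialized from its marginal
soft-threshold regardless, warm starts only accelerate the ω fixed
point, and cold- and warm-started searches agree below 1e−6 in the
selected coefficients (tested).

## Simulator

The generator mirrors the standard benchmark recipe for hub-structured
Gaussian graphical models:

- **Topology.** `hub_network(p, n_hubs, …)` designates hub nodes with
  degrees drawn from 8–12 and attaches them to randomly chosen
  partners; background nodes receive random edges to a mean degree of
  1.5, capped at 5 so that no background node can satisfy the hub rule.
  Defaults reflect sparse interaction networks in which most nodes have
  degree 0–3 and hubs exceed degree 7. Exact literature topologies
  (e.g. protein-interaction subnetworks) are out of scope; the
  generator reproduces their degree structure, not their wiring.
- **Precision matrix.** Edge weights ~ Unif([−1,−0.5] ∪ [0.5,1]) (a
  fair coin over the half-intervals, then uniform within — the mixture
  weighting is not specified in the source recipe), rows scaled by
  1/(1.5·Σ_k |ω̃_ik|) with isolated nodes contributing zero rows,
  symmetrization (A+Aᵀ)/2, unit diagonal, and entries with
  0 < |ω| < 0.1 floored to 0.1·sign(ω). Draws failing the Cholesky
  positive-definiteness check are resampled with an incremented seed
  (up to 100 attempts) rather than eigenvalue-repaired, to stay
  faithful to the recipe.
- **Data.** Σ is the correlation-standardized inverse,
  Σ_ij = (Ω⁻¹)_ij/√((Ω⁻¹)_ii(Ω⁻¹)_jj); rows are i.i.d. N(0, Σ);
  optional observation noise adds N(0, σ_ε²·I) independently.

What the simulator does *not* emulate: non-Gaussian expression
distributions, batch effects, correlated measurement noise, or
networks whose hubs are unknown a priori. Passing recovery tests on
these simulations shows the estimator exploits a correct hub prior
under the assumed model; it does not certify performance on real
microarray data, where the prior may be partial or wrong.

## Evaluation

Confusion counts over all p(p−1)/2 pairs give SEN, SPE, FDR, MISR and
MCC as usually defined. Degenerate denominators use random-
classification conventions: FDR = 0 when nothing is called, MCC = 0
when any of its four factors vanishes. Hubs are identified as nodes
whose degree exceeds both 7 and the 0.95 empirical degree quantile.
The quantile uses the floor ("lower") convention — the largest observed
degree at or below the 0.95 position — under which a sparse network
with a small fraction of high-degree nodes has its quantile at the
background-degree level, so the strict inequality singles out exactly
the designated hubs (e.g. 3 hubs among 44 nodes with a quantile of 7);
interpolating conventions would place the quantile on a hub degree and
contradict that reading.

## Study sizes

The replicated studies in the test suite and acceptance script use
p = 40 genes, 3 hubs, n = 40 samples — the smallest of the network
scales on which hub-aware estimation is meaningfully distinguishable
from hub-blind estimation — with 50 replicates for the main direction
study, 15 per noise level (σ_ε² ∈ {0, 0.1, 0.5}) in the suite, and 15/8
replicates in the acceptance script. These sizes are the package's
choice of a study that a reviewer can rerun quickly; directions
(hub-aware ≥ hub-blind mean MCC, mean α* < 1, MCC non-increasing in
noise) are stable across seeds at these sizes, while the absolute MCC
values are smaller than those reported for larger networks with
hundreds of genes.

## Known limitations

- The pairwise objective is convex in ρ only at fixed ω; the alternating
  scheme carries no global-optimality guarantee, and in the overfit
  regime the ω map can cycle (flagged, never silently accepted).
- GIC consistency arguments assume n growing with p; at p ≈ n the
  criterion is conservative, and the hub-blind model it selects can be
  very sparse.
- The hub penalty treats all hubs alike; per-hub or per-edge weights
  beyond the single α are not implemented.
- EGLASSO model selection is provided through the same GIC machinery
  only via the pairwise route; the likelihood route exposes (λ, α)
  directly.
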