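# Methods

This note documents the statistical procedures implemented in `bilingam`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical conventions that make runs
reproducible.

## Model

Each group k = 1..K observes `n_k` i.i.d. rows of a linear structural
equation model

    X = Bᵀ X + ε,

where `B ∈ R^{p×p}` is the weighted adjacency of a DAG (`b_ij ≠ 0` means
`i → j`) and the errors `ε_i` are mutually independent, continuous and
non-Gaussian with nonzero variance. Acyclicity is equivalent to the
existence of a permutation π rendering `B` strictly lower triangular.
Non-Gaussianity makes π identifiable from observational data; Gaussian
errors would leave entire Markov-equivalence classes indistinguishable.

The estimator constrains the DirectLiNGAM search with an association-based
prior `A^prior ∈ {0, −1}^{p×p}`: 0 excludes the pair in both orientations,
−1 leaves the directed status to be estimated. The prior is symmetric by
construction (association networks are undirected).

## Stage 1 — Gaussianization

Partial-correlation machinery assumes approximately Gaussian marginals.
Each column is mapped through its empirical CDF (average ranks on ties;
convention `rank/(n+1)`), Winsorized to `[δ_n, 1−δ_n]` with

    δ_n = 1 / (4 n^{1/4} √(π log n)),

then through the standard-normal quantile function, and finally rescaled
to unit sample standard deviation (ddof = 1). The truncation constant is
the standard high-dimensional choice for this transform; rescaling keeps
downstream correlation matrices well scaled. The map is invariant to
strictly increasing marginal transformations and preserves ranks exactly
except among the few clipped tail values, which become tied.

An Anderson–Darling normality screen (estimated mean/variance, p-values
from the D'Agostino–Stephens approximation as implemented in statsmodels)
quantifies marginal non-Gaussianity before and after the transform;
constant columns are reported non-testable rather than crashing.

## Stage 2 — Distinct association networks (ψ-learning)

Classical partial correlations condition each pair on all `p − 2`
remaining variables and are ill-posed for `p ≳ n`. The ψ-learning device
replaces the full conditioning set of pair (i, j) with

    S_ij = (nbr(i) ∪ nbr(j)) \ {i, j},

where `nbr(i)` are the top correlation-ranked partners of i, truncated at
a cap (default `⌊n / log n⌋`, the screening size suggested by the
consistency theory for this estimator; exposed as a parameter). If the
union exceeds the cap it is pruned keeping members most correlated with
the pair. The ψ-score is the sample partial correlation of (i, j) given
`S_ij`, computed by inverting the sub-correlation matrix; an
ill-conditioned sub-matrix (condition number > 1e10) receives a 1e-6
ridge with a warning — a documented, negligible bias in exchange for
numerical safety.

Edges are called with the Fisher test `z_ij = √(n − |S_ij| − 3)
atanh(ψ_ij)`, two-sided against N(0, 1), with Benjamini–Hochberg FDR
control at α = 0.05 across all p(p−1)/2 pairs. BH is used uniformly
(rather than the empirical-Bayes multiple-testing variant some ψ-learning
implementations use) for transparency and determinism. `|ψ| = 1` is
clamped to `1 − 1e−12` before `atanh`.

## Stage 3 — Joint association networks (meta-analytic coupling)

Per-edge evidence is shared across groups by a sample-size-weighted
Stouffer combination,

    z_meta = Σ_k w_k z_k / √(Σ_k w_k²),   w_k = √n_k,

followed by linear coupling of each group's z-matrix to the meta signal:

    z'_k = (z_k + λ z_meta) / √(1 + λ² + 2 λ c_k),   c_k = w_k / √(Σ w²).

The denominator is the exact null standard deviation of the numerator:
because `z_meta` contains `z_k` itself with loading `c_k`, dividing only
by `√(1 + λ²)` would leave the null variance at `1 + 2λc_k/(1+λ²)` (≈ 1.58
for K = 3, λ = 1) and the joint test would be strongly anti-conservative —
in simulation it roughly doubled the prior's false-pair count and drove
downstream directed-edge FDR to ~0.5. With the exact normalization the
joint test is correctly sized, and λ = 0 still reduces `E^c` to the
distinct-only decision. λ (default 1) controls shrinkage toward shared
structure; it is a prior-strength knob, not a fitted quantity.

The joint step here is a meta-analytic surrogate for a fully Bayesian
hierarchical construction: it keeps the two properties that matter for the
prior — shared edges are reinforced roughly ∝ √K, group-specific edges are
attenuated by the same coupling — while remaining closed-form,
deterministic and exactly sized.

The prior for group k is the union: `A^prior,k_ij = −1` iff the pair is in
`E^d,k ∪ E^c,k` (either orientation), else 0. With K = 1 the joint step is
skipped and the prior is `E^d` alone (the single-association-prior
variant, available for K > 1 via `prior="distinct"`).

## Stage 4 — Constrained DirectLiNGAM

**Ordering.** The pairwise directionality measure is the maximum-entropy
likelihood ratio: for standardized u, v with correlation ρ and
standardized residuals `r(v|u) = (v − ρu)/√(1−ρ²)`,

    LR(u → v) = H(v) + H(r(u|v)) − H(u) − H(r(v|u)),

with the differential entropy approximated by
`H(u) ≈ (1 + log 2π)/2 − k₁(E log cosh u − γ)² − k₂(E u e^{−u²/2})²`,
k₁ = 79.047, k₂ = 7.4129, γ = 0.37457. The measure is exactly
antisymmetric; perfectly collinear pairs score 0 (no directional
information). At each step the remaining variable maximizing
`−Σ_j min(0, LR_ij)²` over prior-adjacent remaining partners is extracted
(prior-excluded pairs contribute nothing and are never residualized
against each other); its effect is regressed out of its prior-permitted
neighbours; exact score ties break to the lowest variable index so runs
are deterministic. An all-zero prior yields the index order with a
warning.

Ordering runs on the **raw** observations, not the Gaussianized ones: the
non-Gaussianity of the errors is precisely the identification signal, and
the marginal transform used for the prior stages would attenuate it. A
flag (`order_on_transformed`) switches this for sensitivity analysis.

**Weights.** Given the order, each variable j is regressed on its
permitted predecessors `P_j = {i : π(i) < π(j), A^prior_ij = −1}`. The
default is an adaptive lasso: predictors are rescaled by their |OLS|
coefficients and the L1 level is chosen by BIC (LARS path), which prunes
prior pairs that carry no directed effect. Plain restricted OLS
(`mode="restricted-ols"`) is exact on the permitted support but places a
nonzero weight on *every* permitted pair, which in simulation inflates
directed-edge FDR from ~0.03 to ~0.27 at K = 3, p = 40, d = 1; it remains
available for weight-recovery analyses where the support is already
correct. Rank-deficient designs fall back to a 1e-6 ridge with a warning.
The result honours `supp(B̂) ⊆ {A^prior = −1}` and the estimated order by
construction, hence is always acyclic. Under `n < p` the prior keeps every
regression low-dimensional — the structural reason the pipeline still
works in the high-dimensional regime.

## Simulator

The generator emulates the multi-group study design used throughout the
package's benchmarks:

- `G¹`: each node pair admissible under a uniformly random causal order
  carries an edge independently with probability `d/(p−1)` (`d` = mean
  edge degree; expected edge count `pd/2`). The random order prevents the
  variable index from encoding causal position.
- Weights: `Unif(−0.8, −0.3) ∪ (0.3, 0.8)`, equal mass per branch.
- `Gᵏ` for k ≥ 2: `⌊0.05 |E|⌋` edges of `G^{k−1}` removed, the same number
  added at empty positions consistent with a fixed topological order of
  `G^{k−1}` (acyclicity by construction), weights `Unif[0.3, 0.5]`. Added
  positions exclude the just-removed ones within a call, so the stated
  turnover is real; across successive k a deleted edge may reappear.
  Flooring is used for the 5 % counts.
- Noise: `ε ~ χ²(1) − 1` (mean 0, variance 2, strongly right-skewed); rows
  solve `(I − Bᵀ)x = ε` exactly.
- `N` total rows split equally, `n = N/K`.

Default problem sizes in the shipped benchmarks are scaled to desk-size
hardware: K = 3, p = 40, n = 200 (moderate dimension) and K = 5, p = 60,
n = 40 (high dimension), with 10 replicates per cell. What the simulator
does **not** emulate: temporal autocorrelation, task structure, scanner
noise, or inter-subject heterogeneity of real fMRI-derived data — rows are
i.i.d. and groups differ only by the edge-turnover mechanism. Passing
benchmarks therefore demonstrate correctness of the estimator under its
own model assumptions, not performance on real imaging data.

## Metrics and network analysis

- Confusion counts are over all p(p−1) ordered pairs; TPR = TP/(TP+FN),
  FDR = FP/(FP+TP). Sentinels: TPR is NaN with no actual positives, FDR
  is 0 with no predictions.
- SHD counts one operation per differing unordered pair: insertion,
  deletion, or a single flip for a reversed edge.
- Jaccard similarity is over directed edge sets; two empty sets score 1
  (identical graphs).
- Hubs: degree ≥ mean + 2·(population sd) of the chosen degree sequence
  (in/out/total), inclusive; when sd = 0 no node qualifies, since none
  exceeds the average.
- Module flows: entry (A, B) counts directed edges from module A to B.
  Enrichment per block is a one-sided hypergeometric test: population
  p(p−1) ordered pairs, successes `n_A n_B` (minus `n_A` on the diagonal —
  self-loops excluded), draws = total edge count, p = P[X ≥ observed].
  BH-FDR is applied jointly across all M² blocks (intra- and inter-modular
  together) at the single stated α.
- Robustness: stratified subsampling without replacement at given
  fractions, re-running an arbitrary estimator, reporting mean ± sd edge
  counts per group per fraction.

## Numerical conventions and degenerate inputs

- All randomness flows through `numpy.random.Generator`; identical
  configurations produce bit-identical outputs.
- Kahn's algorithm with smallest-index-first tie-breaking defines the
  canonical topological order.
- Constant columns: excluded (non-testable) in the AD screen, an explicit
  error naming the column in the transform and in ordering.
- Edge-addition exhaustion in the perturbation step raises rather than
  silently under-adding.

## Known limitations

- The joint coupling assumes edge-wise evidence is comparable across
  groups after the √n weighting; strongly different group-level
  signal-to-noise would argue for estimated weights.
- The adaptive-lasso BIC selection is per-node; no joint sparsity level is
  enforced across nodes or groups.
- The ordering step is O(p³) pairwise measures in the worst (unrestricted)
  case; the prior's sparsity is what makes large p practical.
- Only marginal Gaussianization is performed; the association stages
  assume the transformed joint distribution is close enough to a Gaussian
  copula for partial correlations to rank edges correctly.
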