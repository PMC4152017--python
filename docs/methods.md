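# Methods

## Problem setting

A drug–ADR association network is a bipartite graph encoded as a binary
incidence matrix `Y` (`n` drugs × `m` ADRs, `Y[d,e] = 1` for a known
association). Prediction means assigning every pair a real score `F[d,e]`
such that unreported true associations rank above true non-associations.
Because reporting is incomplete, zeros are unlabeled rather than negative;
all evaluation is therefore ranking-based (AUC, AUPR) rather than
threshold-based.

## Similarity features

**Topological.** Each feature compares the interaction profiles (neighbour
sets on the opposite side) of two homologous nodes. Bounded features —
Jaccard, GIP, overlap, Dice — already live in [0, 1]. Unbounded features —
common neighbours, neighbours product, Adamic–Adar — are min–max scaled
over off-diagonal entries by default so every feature can serve as a
kernel or blend component on a common scale; `normalize=False` gives raw
values. Conventions for degenerate cases: the diagonal is always 1; a node
with an empty neighbourhood has similarity 0 to every other node (this
matters after cross-validation masking, which can empty a neighbourhood);
Adamic–Adar common neighbours of degree ≤ 1 contribute 0 rather than
dividing by `ln 1`; the GIP bandwidth `γ = γ'/mean(‖y_i‖²)` falls back to
`γ'` on an all-empty side. The overlap coefficient and the Dice
coefficient fill the two feature slots whose exact published forms are
ambiguous in the lineage this package follows; both are entries in a
registry (`topology.FEATURE_REGISTRY`) so an alternate definition can be
swapped in without touching callers.

**Intrinsic.** Chemical similarity arrives as precomputed pair scores
(three-column text). Taxonomy similarity is computed with Lin's measure
under descendant-count information content,
`IC(t) = −ln(desc(t)/desc(root))`, chosen because it is deterministic and
corpus-free; nodes annotated with several terms aggregate by the maximum
over term pairs (the common, optimistic convention — an average-based
aggregation would systematically shrink scores for multi-annotated nodes).
A root-only degenerate hierarchy defines similarity as 1 for identical
terms and 0 otherwise.

**Blending.** Integrated features are convex combinations per side:
`λ_d` weighs drug topology against drug intrinsic similarity (`λ_a`
analogous), and `ω` weighs chemical against taxonomy similarity inside the
drug intrinsic block. Defaults `ω = 0.5`, `λ = 1` (purely topological)
until a grid search says otherwise.

## Predictors

All predictors apply a fixed linear operator (built from `S^d`, `S^a`) to
`Y`; linearity is verified by additivity tests. Defaults: `σ = 1`,
`β = 1`, `w = 0.5` — neutral values on the scale where similarities lie
in [0, 1]; all are grid-searchable.

**RLS.** `F = K(K+σI)⁻¹Y`. The `avg` variant smooths rows and columns
separately and averages. The pair-kernel variants use the Kronecker
product `K^d ⊗ K^a` or Kronecker sum `K^d ⊗ I + I ⊗ K^a`; both share the
eigenbasis `V_d ⊗ V_a`, so the solve is an elementwise spectral filter
(`λμ/(λμ+σ)` or `(λ+μ)/((λ+μ)+σ)`) on the rotated matrix — `O(n³+m³+nm(n+m))`
instead of `O(n³m³)`. Similarity matrices need not be positive
semidefinite (Jaccard-type matrices are not in general), so kernels pass
through a PSD repair first: `shift` adds `(−λ_min+10⁻⁸)I` (default; keeps
off-diagonal structure intact), `clip` zeroes negative eigenvalues,
`off` asserts PSD. The `vec` convention is column-major with drug-major
pair order; it is pinned by dense-oracle tests so a transposition cannot
creep in silently.

**SLP.** Minimizes `‖F−Y‖² + β·vec(F)ᵀL·vec(F)`, closed form
`vec(F) = (I+βL)⁻¹vec(Y)`, with `L` the symmetric normalized Laplacian of
the pair-similarity graph (degrees = row sums, self-similarity included).
For `kp` the pair degrees factorize and the solve is spectral; for `ks`
they do not, so the system is solved by conjugate gradients with
matrix-vector products applied through the factorized structure
(`rtol 1e-12`; the operator is SPD with eigenvalues ≥ 1, so CG converges
quickly). A zero-degree node's Laplacian row is zeroed, which makes its
scores pass through `Y` unchanged — the defined behaviour for nodes
isolated by masking. The unnormalized Laplacian is not exposed; the
normalized form is scale-free, which matters when similarity magnitudes
differ between sides.

**NN.** `F(d,e) = ½[max_{d'≠d} S^d(d,d')Y(d',e) + max_{e'≠e}
S^a(e,e')Y(d,e')]`; an empty or all-zero candidate set contributes 0. The
per-side average mirrors the `avg` kernel variants.

**GWPM.** Row-normalized similarity smoothing per side, mixed by `w`:
the drug-side score of `(d,e)` is the similarity-weighted fraction of
`d`'s neighbours-by-similarity that are associated with `e`. The diagonal
is excluded from both numerator and normalizer — under CV masking a
node's own zeroed entry must not drag its score down. Scores are convex
combinations of `Y` entries, hence in [0, 1] and monotone in `Y`.

**Logistic baseline.** One covariate row per pair: the weighted-profile
score under each topological feature and each intrinsic similarity, plus
both node degrees. Unpenalized maximum-likelihood fit (statsmodels);
perfect separation or non-convergence falls back to a ridge-stabilized
IRLS fit with penalty 10⁻⁶ (logged). Because its covariates depend on
`Y`, the cross-validation driver rebuilds them from the masked matrix
every round.

## Evaluation protocol

Edges and non-edges are partitioned independently into `k` balanced folds
(sizes differ by ≤ 1). Per round, fold edges are zeroed in the training
matrix; every topological feature is recomputed from the masked matrix
(the leak-detection test asserts that a deliberately leaky computation
differs); the predictor is refit; fold edges (label 1) and fold non-edges
(label 0) are scored. One AUC/AUPR is computed per repeat by pooling all
folds' held-out scores; the summary is mean ± sd over `repeats` runs with
fold seeds `seed..seed+repeats−1`. Five repeats by default — the minimum
supporting a stable sd; the per-fold values are also emitted for anyone
who prefers an sd over folds.

AUC is the Mann–Whitney statistic (ties count ½). AUPR is
non-interpolated average precision; tied-score blocks are handled by
placing the block's positives at evenly spaced fractional ranks within
it, which reduces exactly to standard AP on tie-free input and avoids the
optimistic bias of putting all tied positives first. Trapezoidal PR
integration is available behind a flag.

Grid search enumerates `(λ_d, λ_a)` (optionally `ω`) on a step-0.1 grid
maximizing CV AUC (switchable to AUPR), one CV repeat per grid point with
a fold seed shared across candidates so all candidates face identical
splits; ties break toward larger `λ_d`, then `λ_a`. Prospective
evaluation trains on the full earlier snapshot and labels all its
non-edges by the later snapshot. Degree stratification splits non-edge
scores at a degree threshold (default 40, a natural hub cutoff for
networks with average degree ≈ 20) into low–low/high–low/low–high/high–high
strata.

Non-edges are tracked as flat indices into `Y`, never materialized as
pair-object lists, so full CV on a 404 × 461 network stays cheap.

## Synthetic data

The generator emulates the statistical structure the methods assume:
a sparse bipartite network with right-skewed degrees plus side
similarities correlated with the structure that generated the edges.
Drugs and ADRs receive unit latent vectors scattered
(`sd 0.25`) around `latent_dim = 10` random archetype directions whose
popularity decays geometrically — popular archetypes create hubs, rare
ones create the long low-degree tail (drug-degree skewness ≈ 0.7 at the
defaults). Edges are Bernoulli with probability
`logistic((u_d·v_a − θ)/τ)`, `τ = 0.08`, with `θ` calibrated by bisection
so the expected density hits the target (hard error if the calibrated
expectation misses by > 5%; the binomial realization is only warned about
when outside 10%). Similarities are `clip(u_i·u_j + ε, 0, 1)` with
symmetric Gaussian noise `ε` (`sd 0.05` by default), diagonal forced to 1.
Defaults (80 × 90, density 0.05, seed 1) were fixed once as the package's
study conditions: ten latent classes stand in for major
therapeutic/toxicity groupings, and the noise level keeps the similarity–
Gram correlation around 0.95, the regime where intrinsic side information
is informative but not a giveaway.

What the generator does *not* emulate: the heavy right tail of real
pharmacovigilance degree distributions (hubs with hundreds of edges),
reporting biases correlated with drug age or usage, and intrinsic
similarities whose noise is structured (chemical series, MedDRA siblings)
rather than i.i.d. Passing recovery tests on this generator therefore
demonstrates algorithmic correctness and sane signal use, not expected
performance on real FAERS/SIDER-derived networks.

## Numerical choices and limitations

* Eigendecompositions use symmetric solvers (`eigh`); kernel PSD
  tolerance is 10⁻⁸ throughout.
* RLS `kp/ks` with the default `shift` repair changes the kernel the
  predictor sees (by a diagonal ridge); with heavily indefinite
  similarity matrices `clip` may be preferable.
* `read_pairwise_similarity` fills unlisted pairs with 0 and resolves
  conflicting `(a,b)`/`(b,a)` records by the maximum, warning either way;
  labels outside the network's node universe are dropped with a warning.
* Edge-list headers are auto-detected (first record non-numeric and its
  labels never reappear); ambiguous single-record files are treated as
  data.
* The logistic baseline refits once per fold on all non-held-out pairs,
  which is `O(nm)` rows per fit; for very large networks subsampling
  non-edges would be needed.
* `grid_search_weights` with a single repeat per point can pick a
  neighbouring grid cell under CV noise; the tie rule only disambiguates
  exact ties.
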