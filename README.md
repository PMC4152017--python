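# adrlink

Bipartite link prediction of drug–adverse-drug-reaction (ADR) associations.

Pharmacovigilance networks record which drugs are known to cause which
adverse reactions. Given such a network — a binary incidence matrix
`Y ∈ {0,1}^{n×m}` over `n` drugs and `m` ADRs — the task is to rank the
unobserved (drug, ADR) pairs by how likely they are to be true but
not-yet-reported associations. `adrlink` implements the full pipeline for
this problem: similarity construction, a family of predictors, and the
evaluation protocol. It is aimed at computational pharmacology researchers
who want to benchmark network-based ADR predictors, and at anyone studying
bipartite link prediction with side information.

## The model

Two kinds of node-pair similarity feed the predictors:

* **Topological features**, computed from neighbour sets in the network
  itself: Jaccard coefficient, Gaussian interaction profile (GIP) kernel
  `exp(−γ‖y_x − y_y‖²)` with `γ` normalized by the mean squared profile
  norm, overlap coefficient, neighbours product, common neighbours,
  Adamic–Adar `Σ_z 1/ln deg(z)`, and the Dice coefficient.
* **Intrinsic features**, from outside the network: chemical-structure
  scores between drugs, and Lin information-content semantic similarity
  `sim(t₁,t₂) = 2·IC(lca)/(IC(t₁)+IC(t₂))` over the ATC (drug) and MedDRA
  (ADR) term hierarchies.

Similarities may be blended convexly per side,
`S = λ·S_topological + (1−λ)·S_intrinsic`, giving *integrated* features.

The predictors all reduce to a linear operator applied to `Y`:

* **RLS** — kernel regularized least squares `F = K(K+σI)⁻¹Y`, with the
  kernel per side (`avg`) or over pairs via the Kronecker product (`kp`)
  or Kronecker sum (`ks`) of the side kernels. The pair solves use the
  factorized eigenbasis and never materialize the `nm×nm` matrix.
* **SLP** — semi-supervised link propagation
  `vec(F) = (I+βL)⁻¹vec(Y)` with `L` the symmetric normalized Laplacian of
  the pair-similarity graph (`kp`, `ks`, `avg` variants).
* **NN** — nearest-neighbour memory scores.
* **GWPM** — the general weighted profile method:
  `F = w·WP_d + (1−w)·WP_a` where `WP_d(d,e) = Σ_{d'≠d} S^d(d,d')Y(d',e) /
  Σ_{d'≠d} S^d(d,d')`, i.e. row-normalized similarity smoothing of `Y`
  per side.
* **logistic** — a per-pair covariate logistic-regression baseline
  (weighted-profile scores of every feature plus node degrees).

Evaluation follows the edge-masking protocol: interacting and
non-interacting pairs are each split into ten folds; per round the held-out
edges are zeroed in `Y`, every topological feature is recomputed from the
masked matrix, and the held-out pairs are scored. Performance is
Mann–Whitney AUC and non-interpolated average precision (AUPR), pooled per
repeat, mean ± sd over repeats. Prospective evaluation trains on an early
snapshot and labels its non-edges by a later one. Blend weights are chosen
by exhaustive grid search, and predictions can be stratified by node degree
to expose the degree bias of topological evidence.

## Worked example

The built-in generator plants latent archetype structure, samples a sparse
right-skewed network from it, and derives side similarities from the same
latent factors — so held-out edges are genuinely recoverable:

```python
import adrlink as al

net, Sd, Sa, truth = al.generate(al.SyntheticSpec())   # 80 x 90, ~5% density
print(net.n_drugs, net.n_adrs, net.n_edges)            # 80 90 358

res = al.cross_validate(
    net, Sd, Sa, feature=None,                          # intrinsic only
    config=al.PredictorConfig(algorithm="gwpm"),
    k=10, seed=1, repeats=3,
)
print(f"AUC {res.auc:.3f} ({res.auc_sd:.3f})  AUPR {res.aupr:.3f}")
# AUC 0.904 (0.001)  AUPR 0.283
```

An AUC of 0.904 means a held-out true association outranks a random
non-association 90% of the time; the much lower AUPR reflects the ~20:1
class imbalance among test pairs. The same run through the CLI:

```bash
adrlink simulate --out-dir data/
adrlink cv --network data/network.tsv --drug-sim data/drug_sim.tsv \
    --adr-sim data/adr_sim.tsv --feature none --algorithm gwpm \
    --seed 1 --repeats 3 --out-dir data/cv
# AUC 0.9036 (0.0009)  AUPR 0.2831 (0.0016)
```

Real data plugs in the same way: `adrlink stats --network edges.tsv`,
`adrlink features --network edges.tsv --feature jaccard --out S.tsv`,
`adrlink predict ...`, `adrlink gridsearch ...`, `adrlink prospective ...`.
Edge lists are two-column TSV/CSV/XLSX; similarity files are three-column
`label label score` text.

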