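# Methods

## Model

The package predicts lincRNA–disease associations from a heterogeneous
network.  Let `X̂ ∈ {0,1}^{n_l × n_d}` be the observed lincRNA–disease
association matrix, `Ŷ ∈ {0,1}^{n_g × n_d}` the gene–disease associations,
`Ẑ ∈ {0,1}^{n_g × n_l}` the gene–lincRNA associations (gene i – lincRNA j
linked iff they share at least one disease), `W^[g]` the weighted
genetic-interaction network over genes and `W^[l]` the lincRNA
co-expression network.  For a network `W` with degree matrix `D`, the
normalized Laplacian is `L = I_d − D^{−1/2} W D^{−1/2}`, where `I_d` is the
identity restricted to nonzero-degree nodes and `d^{−1/2} := 0` for
isolated nodes, so isolated entities contribute nothing to the regularizer.

The model factorizes `X̂ ≈ B F` with non-negative factors
(`B: n_l × r`, `F: r × n_d`) by minimizing

    L(B, F) = ½‖X̂ − BF‖_F²  +  α·Tr(B' L^[l] B)  +  (β/2)‖BF − T‖_F² ,
    B ≥ 0, F ≥ 0,

where `T = Ẑ' W^[g] Ŷ` is the **path-weight matrix**: `T_ld` sums the
weights of all lincRNA → gene → gene-network → disease paths from lincRNA
l to disease d.  The graph term pulls latent representations of
co-expressed lincRNAs together; the path term asks the reconstruction to
agree with the network evidence.  The underlying biological assumptions
are (i) associations are approximately low-rank (a few latent disease
programs), (ii) co-expressed lincRNAs share programs, and (iii) an
association is more plausible the more gene-network paths support it.

A note on orientation: with `Ẑ` stored genes × lincRNAs, the product
`Ẑ W^[g] Ŷ` is not conformable; the implementation uses `Ẑ'·W^[g]·Ŷ`,
the unique orientation conformable with `B F` (lincRNAs × diseases).

## Optimization

Direct minimization is non-convex; the optimizer alternates multiplicative
updates derived from the Karush–Kuhn–Tucker conditions.  The gradients are

    ∇_B L = (1+β)·B F F' − X̂ F' − β·T F' + 2α·L^[l] B
    ∇_F L = (1+β)·B'B F − B'X̂ − β·B'T .

Because `L^[l]` is indefinite in sign pattern (non-positive off-diagonal),
it is split into its non-negative parts — `I_d` into the denominator and
the normalized adjacency `W̄ = D^{−1/2} W D^{−1/2}` into the numerator —
the standard device of graph-regularized NMF.  The updates are

    B ← B ⊙ [X̂F' + β·TF' + 2α·W̄ B] ⊘ [(1+β)·B F F' + 2α·I_d B + ε]
    F ← F ⊙ [B'X̂ + β·B'T]          ⊘ [(1+β)·B'B F + ε] .

With non-negative inputs these keep the factors non-negative and never
increase the objective (verified as a property over a grid of random
instances × (α, β) combinations).  With α = β = 0 they reduce exactly —
bit for bit, given a shared seed — to the classical two-factor
multiplicative NMF rules.

Numerical choices:

* **Initialization** — entries i.i.d. uniform(0,1) scaled by
  `sqrt(mean(X̂)/r)`, from a seeded generator: reproducible and on the
  data's magnitude.
* **Guard** — `ε = 1e-12` added to the denominators; an exactly-zero row
  or column of a factor is an absorbing state (a known property of
  multiplicative updates) and stays zero.
* **Stopping** — relative objective change `|O_t − O_{t−1}| / max(O_{t−1},
  ε) < tol` (default `1e-6`) or `max_iter` (default 200) sweeps.
* **Prediction** — scores `X = B F` are clipped to [0, 1] by default so
  the mean absolute error against binary labels is calibrated; raw scores
  are available with `clip=False`.

### Parameters

| parameter | default | meaning |
|---|---|---|
| `r` | 8 | latent dimension; should be well below min(n_l, n_d) (warned otherwise) |
| `alpha` | 1.0 | weight of the co-expression graph regularizer |
| `beta` | 1.0 | weight of the path regularizer |
| `max_iter` / `tol` | 200 / 1e-6 | stopping rule |
| `epsilon` | 1e-12 | denominator guard |
| `normalize_gene_net` | False | use `W̄^[g]` instead of raw `W^[g]` in `T` |
| `clip_predictions` | True | clip scores to the label scale |
| `threshold` | 0.5 | co-expression \|Pearson r\| cutoff |
| `theta` | 0.5 | label-propagation trade-off |

`alpha = beta` reflects the assumption that the two networks are equally
informative; 1.0 is a robust middle of the useful range.  Note the scale
of `T` grows with network size and density, so on much larger networks
`beta` should shrink correspondingly (or `normalize_gene_net` be enabled);
the package does not rescale `T` silently.

The co-expression network uses the absolute Pearson correlation on raw
expression with a hard threshold (default 0.5) and keeps `|r|` as the edge
weight: the graph term needs non-negative weights and magnitude preserves
more structure than binarizing.  No soft-thresholding or p-value filtering
is attempted.

## Baselines

* **Plain NMF** — the fit with α = β = 0 (exposed as `plain_nmf`).
* **Label propagation** — minimizes `θ·Tr(X'L^[l]X) + (1−θ)‖X − X̂‖_F²`;
  the unique minimizer `X* = (1−θ)(θL + (1−θ)I)^{−1} X̂` is computed by a
  positive-definite solve (columns decouple, so solving all diseases at
  once equals per-disease propagation).  An equivalent fixed-point
  iteration `X ← θW̄X + (1−θ)X̂` (isolated rows pinned to `X̂`) is kept as
  a cross-check.  θ defaults to 0.5.

Other published comparison methods (joint multi-view factorizations,
non-smooth NMF variants, random-walk rankers) are out of scope; the
evaluation harness accepts externally supplied score matrices instead.

## Evaluation protocols

`Accuracy = 1 − MAE` with MAE the mean absolute difference between labels
and (clipped) scores over the test cells τ; RMSE is the root mean squared
error over τ; RSS is the residual sum of squares over **all** cells and is
used for model selection on the training reconstruction.

* **Leave-one-disease-out** — for each disease the whole column of `X̂` is
  zeroed, the model refit, and the full held-out column (both classes —
  MAE needs both) scored; repeated with fresh seeds (default 50,
  configurable) and aggregated as mean ± sd over folds and repeats.  Since
  all folds have `n_l` cells, the fold-mean and cell-mean accuracies
  coincide; both are reported.  A per-positive-cell granularity is
  available behind a flag.  The side information (`Ẑ`, `W^[g]`, `Ŷ`,
  co-expression) stays fixed across folds, mirroring how such catalogs are
  used in practice.
* **External (temporal) validation** — fit on the associations known
  before a cut-off, score the cells whose associations were reported
  later; overlap between training positives and test cells is rejected as
  leakage.
* **Sweeps** — one seeded refit per grid point over `r`, `alpha_beta`
  (α = β jointly) or the iteration budget, emitting plot-ready TSV.

## Synthetic data

The generator plants the exact structure the model assumes, with one
latent dimension shared by all views: exponential factors `B*`, `F*` give
clean scores `S = B*F*`, binarized at the quantile matching the target
density (density-targeted binarization keeps instance difficulty
controlled across sizes); expression is `B*·(random loadings) + Gaussian
noise` over 22 samples (the tissue count of the human lincRNA catalog this
pipeline would ingest); `Ŷ` assigns each disease a **disjoint** module of
genes; the gene network is **disease-modular** (edge probability 0.8
within a module, 0.001 background, uniform weights); `Ẑ` follows the
shared-disease rule; finally a fraction (default 1%) of `X̂` cells is
flipped as label noise.

The modular construction is deliberate.  For a fully random gene network
the path weight factorizes as `T_ld ≈ (genes sharing a disease with l) ×
(mean path mass into d)` — a rank-one popularity surface with *no*
association-specific term; and any gene associated with two diseases acts
as a bridge giving non-associated pairs path weights as large as true
ones.  With disjoint modules and a modular network, a true pair (l, d)
gains `≈ m(m−1)·p_in·E[w]` of path weight through disease d's own module
(m genes per disease), while a non-pair only collects the background
`≈ n_ld·m²·p_out·E[w]`; the defaults put the two an order of magnitude
apart, which is what "planted path signal" should mean.  Defaults: 60
lincRNAs × 100 genes × 30 diseases, rank 4, association density 0.05,
3 genes per disease — a full cross-validation runs in seconds.  A
`paper_scale_config` preset reproduces the shape ratio of the real
catalogs (562/13425/645) scaled down 10×.

What the generator does **not** emulate: RNA-seq count noise and tissue
structure, overlapping gene–disease annotations (real genes are
pleiotropic; the disjoint modules are an idealization), disease ontology
relations, and annotation biases of curated databases.  Passing tests
therefore show the method recovers the structure it models, not that it
matches any real-data figure.

`temporal_split` holds out a random fraction of positives while
guaranteeing each disease keeps at least one training positive (re-drawn
when violated, with a deterministic greedy fallback that only removes
cells from columns with two or more remaining positives).

`exact_rank_instance` provides the optimizer benchmark: a noiseless
rank-r matrix whose factors carry per-program *marker* rows and columns
(anchor structure).  Generic random exact-rank instances are a poor
optimizer benchmark here because multiplicative updates exhibit a
notoriously slow ~1/t error tail near factor-permutation saddles —
measured on such instances the error can still sit near 1e-3 after 10⁴
sweeps without this being an implementation defect.  The anchored
instances are essentially unique and well-conditioned; on them the
optimizer reaches < 1e-3 relative error within 500 sweeps across seeds.

## Known limitations

* Multiplicative updates converge slowly near boundaries: entries decaying
  to zero leave a small, slowly vanishing KKT residual (the residual is
  ~1e-12 on interior optima of the plain model but only ~1e-3..1e-2 with
  active regularizers at practical budgets).
* Tight tolerances need budgets far beyond the practical default: on the
  default synthetic bundle the relative objective change falls below 1e-6
  only after ~1300–1700 sweeps, while the score ranking stabilizes within
  ~100–200.
* Fitting *binarized* associations cannot recover pre-binarization
  magnitudes: on noiseless bundles the correlation between `B F` and the
  clean scores is moderate (~0.6–0.75), with the weakest latent factor
  only partially identified.  Score *ranking* of planted positives over
  zeros is nevertheless strong, which is what the prediction task uses.
* The raw path target's scale couples `beta` to network size; cross-study
  comparability of `beta` values is limited.
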