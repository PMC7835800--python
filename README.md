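# crnmf — co-regularized NMF for lincRNA–disease association prediction

Long intergenic non-coding RNAs (lincRNAs) regulate many complex diseases,
but experimentally validated lincRNA–disease associations are scarce and
expensive to obtain.  `crnmf` predicts unobserved associations
computationally by integrating a heterogeneous network: the known
lincRNA–disease associations, lincRNA co-expression, gene–disease
associations, gene–lincRNA links and the gene genetic-interaction network.
It is intended for computational biologists who have (or can simulate)
these matrices and want ranked candidate associations plus a rigorous
evaluation harness.

## Model

With `X̂ ∈ {0,1}^{n_l×n_d}` the observed associations, the package fits
non-negative factors `B` (lincRNAs × r) and `F` (r × diseases) minimizing

```
½‖X̂ − BF‖²_F + α·Tr(B′L⁽ˡ⁾B) + (β/2)‖BF − Ẑ′W⁽ᵍ⁾Ŷ‖²_F ,   B, F ≥ 0
```

where `L⁽ˡ⁾` is the normalized Laplacian of the lincRNA co-expression
network (the graph term pulls co-expressed lincRNAs toward similar latent
representations) and `T = Ẑ′W⁽ᵍ⁾Ŷ` sums the weights of all
lincRNA → gene → gene-network → disease paths (the path term asks the
reconstruction to agree with that network evidence).  Optimization uses
monotone multiplicative updates; predictions are `X = BF`, clipped to
[0, 1].  Baselines (plain NMF, network label propagation), metrics
(MAE / Accuracy / RMSE / RSS), leave-one-disease-out cross-validation, a
temporal external-validation split, parameter sweeps and a synthetic-data
generator with planted structure are included.  See `docs/methods.md` for
the full account.

## Worked example

```python
from crnmf import CrnmfConfig, fit, leave_one_disease_out, predict, prepare_bundle
from crnmf.simulate import SimulationConfig, generate

bundle, truth = generate(SimulationConfig(seed=1))   # synthetic heterogeneous network
lap, target = prepare_bundle(bundle)                 # Laplacian + path-weight matrix

config = CrnmfConfig(r=8, alpha=1.0, beta=1.0, seed=1)
result = fit(bundle.x, lap, target, config)
print(f"fit: {result.iterations} iterations, "
      f"objective {result.objective[0]:.1f} -> {result.objective[-1]:.1f}")

scores = predict(result.factors)
pos = bundle.x.values > 0
print(f"mean score on known associations: {scores.values[pos].mean():.3f}")
print(f"mean score elsewhere:             {scores.values[~pos].mean():.3f}")

for method in ("crnmf", "nmf", "lp"):
    report = leave_one_disease_out(bundle, method, config, repeats=3)
    agg = report.aggregate
    print(f"LOOCV {method:5s} accuracy = "
          f"{agg['accuracy_mean']:.3f} ± {agg['accuracy_sd']:.3f}")
```

Output:

```
fit: 200 iterations, objective 469.9 -> 134.4
mean score on known associations: 0.825
mean score elsewhere:             0.018
LOOCV crnmf accuracy = 0.969 ± 0.026
LOOCV nmf   accuracy = 0.941 ± 0.068
LOOCV lp    accuracy = 0.941 ± 0.068
```

The fitted model scores known associations ~0.83 on average versus ~0.02
for unobserved pairs.  Under leave-one-disease-out cross-validation —
where *every* association of the held-out disease is removed before
refitting — the co-regularized model stays ahead of the baselines because
the path and co-expression evidence still points at the deleted column;
plain NMF and label propagation have no signal for an all-zero column and
fall back to predicting zeros (accuracy ≈ 1 − column density).

## Command line

The same pipeline is scriptable:

```sh
crnmf simulate --seed 1 --out data/
crnmf fit --x data/x.tsv --y data/y.tsv --z data/z.tsv \
          --gene-net data/gene_net.tsv --lincrna-expr data/expression.tsv \
          --r 8 --alpha 1 --beta 1 --seed 1 --out fit/
crnmf predict --fit-dir fit/ --out scores.tsv
crnmf evaluate-loocv --method crnmf --repeats 3 ... --out report/
crnmf sweep --param r --grid 3,6,9,12 ... --out sweep.tsv
```

External data enters as TSV pair lists (associations), edge lists
(networks) with `--pairs`, or labeled matrices; entity identifiers are
strings throughout and all inputs are aligned by identifier intersection.

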