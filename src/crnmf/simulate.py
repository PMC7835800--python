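"""Synthetic heterogeneous-network instances with planted structure.

The generator emulates the statistical structure the model assumes: a
low-rank lincRNA-disease association matrix, lincRNA expression whose
co-expression recovers latent-factor proximity, and a gene network whose
lincRNA → gene → gene → disease path weights genuinely concentrate on the
planted associations.

Construction, for a shared latent dimension ``r_true``:

1. exponential factors B* (lincRNAs x r_true) and F* (r_true x diseases);
   the clean score matrix S = B*F* is binarized at the quantile hitting the
   target association density, giving X̂;
2. lincRNA expression = B*·(random loadings) + Gaussian noise, so Pearson
   co-expression reflects shared dominant factors;
3. gene-disease associations Ŷ: each disease gets a *disjoint* module of
   genes (a gene belongs to at most one disease), sized to the target
   density;
4. the gene genetic-interaction network is *disease-modular*: gene pairs
   sharing a disease (per Ŷ) get an edge with high probability, all other
   pairs with a low background probability — a random uniform weight either
   way.  Without the modular structure in (3)-(4) the path-weight matrix
   Z'·W·Y degenerates into a rank-one popularity surface carrying no
   association-specific signal, and genes spanning two diseases act as
   bridges that give non-associated pairs path weights as large as true
   ones;
5. gene-lincRNA associations Ẑ follow the shared-disease rule applied to Ŷ
   and the clean X̂, so path weights correlate with the planted positives;
6. finally a fraction of X̂ cells is flipped (label noise).

Everything is driven by one seed; identical seeds give identical bundles.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Tuple

import numpy as np
import pandas as pd

from .datatypes import (
    AssociationMatrix,
    DataBundle,
    EntityIndex,
    ValidationError,
    WeightedNetwork,
)
from .evaluation import TestMask
from .networks import build_gene_lincrna_associations


@dataclass
class SimulationConfig:
    """Study conditions of the synthetic generator.

    Defaults are sized so a full cross-validation runs in seconds: 60
    lincRNAs, 100 genes, 30 diseases, 22 expression samples (the tissue
    count of the human lincRNA catalog the real pipeline would ingest).
    Densities give each lincRNA ~1.5 diseases and each disease a disjoint
    module of 3 genes, keeping the path signal-to-background ratio large
    (see the methods note); ``noise`` both flips that fraction of
    association cells and sets the relative sd of the expression noise.
    """

    n_lincrnas: int = 60
    n_genes: int = 100
    n_diseases: int = 30
    r_true: int = 4
    n_samples: int = 22
    density_x: float = 0.05
    density_y: float = 0.03
    module_edge_prob: float = 0.8
    background_edge_prob: float = 0.001
    noise: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.r_true > min(self.n_lincrnas, self.n_diseases):
            raise ValidationError("r_true must be <= min(n_lincrnas, n_diseases)")
        for name in ("density_x", "density_y"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValidationError(f"{name} must lie in (0, 1), got {v}")
        for name in ("module_edge_prob", "background_edge_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        if self.noise < 0:
            raise ValidationError("noise must be >= 0")


def paper_scale_config(seed: int = 0) -> SimulationConfig:
    """A benchmark preset with the real catalogs' shape ratio scaled down 10x
    (562 lincRNAs / 13425 genes / 645 diseases -> 56 / 1342 / 64)."""
    return SimulationConfig(n_lincrnas=56, n_genes=1342, n_diseases=64,
                            r_true=6, density_y=0.01, seed=seed)


@dataclass
class GroundTruth:
    """Planted quantities returned alongside a generated bundle."""

    b_true: np.ndarray
    f_true: np.ndarray
    scores: np.ndarray          # clean pre-binarization score matrix B*F*
    x_clean: np.ndarray         # binarized X̂ before label noise
    flipped_cells: List[Tuple[int, int]]


def _ids(prefix: str, n: int) -> Tuple[str, ...]:
    width = max(3, len(str(n - 1)))
    return tuple(f"{prefix}{i:0{width}d}" for i in range(n))


def generate(config: SimulationConfig = None) -> Tuple[DataBundle, GroundTruth]:
    """Generate a heterogeneous-network bundle with planted low-rank and
    path structure (see the module docstring for the construction)."""
    cfg = config if config is not None else SimulationConfig()
    rng = np.random.default_rng(cfg.seed)
    n_l, n_g, n_d, r = cfg.n_lincrnas, cfg.n_genes, cfg.n_diseases, cfg.r_true

    # (1) planted low-rank associations
    b_true = rng.exponential(1.0, size=(n_l, r))
    f_true = rng.exponential(1.0, size=(r, n_d))
    scores = b_true @ f_true
    cut = np.quantile(scores, 1.0 - cfg.density_x)
    x_clean = (scores > cut).astype(float)
    if x_clean.sum() == 0:
        raise ValidationError(
            f"density_x={cfg.density_x} yields no positive associations"
        )

    # (2) expression consistent with the planted factors
    loadings = rng.exponential(1.0, size=(r, cfg.n_samples))
    expr = b_true @ loadings
    if cfg.noise > 0:
        expr = expr + rng.normal(0.0, cfg.noise * expr.std(), size=expr.shape)

    # (3) gene-disease associations: disjoint disease modules
    genes_per_disease = max(1, int(round(cfg.density_y * n_g)))
    if genes_per_disease * n_d > n_g:
        raise ValidationError(
            f"density_y={cfg.density_y} needs {genes_per_disease * n_d} "
            f"distinct gene slots but only {n_g} genes exist"
        )
    assigned = rng.permutation(n_g)[: genes_per_disease * n_d]
    y = np.zeros((n_g, n_d))
    for d in range(n_d):
        y[assigned[d * genes_per_disease:(d + 1) * genes_per_disease], d] = 1.0

    # (4) disease-modular gene genetic-interaction network
    share = (y @ y.T) > 0
    prob = np.where(share, cfg.module_edge_prob, cfg.background_edge_prob)
    upper = np.triu(rng.random((n_g, n_g)) < prob, k=1)
    weights = np.where(upper, rng.uniform(0.0, 1.0, size=(n_g, n_g)), 0.0)
    weights = weights + weights.T

    lincrna_ids = _ids("l", n_l)
    gene_ids = _ids("g", n_g)
    disease_ids = _ids("d", n_d)
    lincs = EntityIndex("lincRNA", lincrna_ids)
    genes = EntityIndex("gene", gene_ids)
    diseases = EntityIndex("disease", disease_ids)

    x_am_clean = AssociationMatrix(lincs, diseases, x_clean)
    y_am = AssociationMatrix(genes, diseases, y)
    gene_net = WeightedNetwork(genes, weights)

    # (5) gene-lincRNA associations from the clean planted structure
    z_am = build_gene_lincrna_associations(y_am, x_am_clean)

    # (6) label noise
    x_noisy = x_clean.copy()
    flipped: List[Tuple[int, int]] = []
    n_flip = int(round(cfg.noise * n_l * n_d))
    if n_flip > 0:
        flat = rng.choice(n_l * n_d, size=n_flip, replace=False)
        for idx in flat:
            i, j = divmod(int(idx), n_d)
            x_noisy[i, j] = 1.0 - x_noisy[i, j]
            flipped.append((i, j))

    expression = pd.DataFrame(
        expr, index=list(lincrna_ids),
        columns=[f"t{s:02d}" for s in range(cfg.n_samples)],
    )
    bundle = DataBundle(
        x=AssociationMatrix(lincs, diseases, x_noisy),
        y=y_am,
        z=z_am,
        gene_net=gene_net,
        expression=expression,
    )
    truth = GroundTruth(b_true, f_true, scores, x_clean, flipped)
    return bundle, truth


def exact_rank_instance(
    n_lincrnas: int = 16,
    n_diseases: int = 10,
    r: int = 3,
    seed: int = 0,
    anchor_weight: float = 8.0,
    anchor_blocks: int = 2,
) -> Tuple[AssociationMatrix, np.ndarray, np.ndarray]:
    """A noiseless, exactly rank-``r`` association score matrix B*·F*.

    Each latent program gets ``anchor_blocks`` marker lincRNAs and marker
    diseases that load on it alone (weight ``anchor_weight``); all other
    loadings are exponential.  The anchors make the factorization
    essentially unique and well-conditioned, so the instance is a sharp
    optimizer benchmark: multiplicative updates have a notoriously slow
    ~1/t tail near the factor-swap saddles of generic instances, which the
    anchor structure avoids.

    Returns the (real-valued) matrix plus the planted factors.
    """
    if anchor_blocks * r > min(n_lincrnas, n_diseases):
        raise ValidationError("anchor blocks do not fit the requested shape")
    rng = np.random.default_rng(seed)
    b = rng.exponential(1.0, (n_lincrnas, r))
    f = rng.exponential(1.0, (r, n_diseases))
    for k in range(anchor_blocks):
        b[k * r:(k + 1) * r, :] = np.eye(r) * anchor_weight + 0.05
        f[:, k * r:(k + 1) * r] = np.eye(r) * anchor_weight + 0.05
    x = b @ f
    am = AssociationMatrix(
        EntityIndex("lincRNA", _ids("l", n_lincrnas)),
        EntityIndex("disease", _ids("d", n_diseases)),
        x,
    )
    return am, b, f


def temporal_split(
    bundle: DataBundle, holdout_fraction: float, seed: int = 0
) -> Tuple[AssociationMatrix, TestMask]:
    """Hold out a random fraction of positive cells, emulating associations
    reported only after a temporal cut-off.

    Every disease that has any training positives keeps at least one: the
    draw is retried when the constraint fails and, as a deterministic
    fallback, cells are picked greedily from columns that still have two or
    more remaining positives.
    """
    x = bundle.x.values
    positives = np.argwhere(x > 0)
    n_hold = int(round(holdout_fraction * len(positives)))
    if n_hold < 1:
        raise ValidationError(
            "hold-out mask is empty; increase holdout_fraction"
        )
    if n_hold >= len(positives):
        raise ValidationError("cannot hold out every positive association")
    rng = np.random.default_rng(seed)
    col_counts = np.bincount(positives[:, 1], minlength=x.shape[1])
    chosen = None
    for _ in range(50):
        idx = rng.choice(len(positives), size=n_hold, replace=False)
        held = np.bincount(positives[idx, 1], minlength=x.shape[1])
        if np.all((col_counts - held > 0) | (col_counts == 0)):
            chosen = idx
            break
    if chosen is None:  # greedy fallback, deterministic given the seed
        order = rng.permutation(len(positives))
        remaining = col_counts.copy()
        picked = []
        for k in order:
            col = positives[k, 1]
            if remaining[col] >= 2:
                picked.append(k)
                remaining[col] -= 1
                if len(picked) == n_hold:
                    break
        if len(picked) < n_hold:
            raise ValidationError(
                "cannot hold out the requested fraction while keeping one "
                "training positive per disease"
            )
        chosen = np.asarray(picked)
    mask = TestMask(tuple((int(positives[k, 0]), int(positives[k, 1]))
                          for k in chosen))
    train = bundle.x.copy()
    rows, cols = mask.indices()
    train.values[rows, cols] = 0.0
    return train, mask
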