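"""The co-regularized NMF model and its multiplicative-update optimizer.

The model approximates the observed lincRNA-disease association matrix
``X̂ ≈ B F`` with non-negative factors while two regularizers couple the
factorization to the rest of the heterogeneous network:

* a graph regularizer ``α·Tr(B' L B)`` over the lincRNA co-expression
  network, pulling latent representations of co-expressed lincRNAs together
  (L is the normalized Laplacian), and
* a path regularizer ``(β/2)·||B F − T||_F²`` with the path-weight matrix
  ``T = Z' W Y``, encoding support for an association along
  lincRNA → gene → gene-network → disease paths.

The optimizer alternates multiplicative updates of B and F derived from the
KKT conditions of the objective

    L(B, F) = ½||X̂ − BF||_F² + α·Tr(B' L B) + (β/2)||BF − T||_F²

splitting the Laplacian into its non-negative parts (identity part in the
denominator, normalized adjacency in the numerator), the standard device of
graph-regularized NMF.  With non-negative inputs the updates keep both
factors non-negative and never increase the objective.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .datatypes import (
    AssociationMatrix,
    EntityIndex,
    NormalizedLaplacian,
    NumericalError,
    ValidationError,
    WeightedNetwork,
)
from .networks import build_normalized_laplacian


@dataclass
class CrnmfConfig:
    """Hyper-parameters of the model and optimizer.

    r : latent dimension (number of features); should be well below
        min(n_lincRNAs, n_diseases).
    alpha : weight of the co-expression graph regularizer.
    beta : weight of the gene-network path regularizer.
    max_iter, tol : stopping rule — relative objective change below ``tol``
        or ``max_iter`` full update sweeps.
    seed : seed for the factor initialization.
    epsilon : denominator guard inside the multiplicative updates.
    normalize_gene_net : use the degree-normalized gene adjacency in the
        path target instead of the raw weights.
    clip_predictions : clip predicted scores into [0, 1] so they live on the
        scale of the binary labels.
    """

    r: int = 8
    alpha: float = 1.0
    beta: float = 1.0
    max_iter: int = 200
    tol: float = 1e-6
    seed: int = 0
    epsilon: float = 1e-12
    normalize_gene_net: bool = False
    clip_predictions: bool = True

    def __post_init__(self) -> None:
        if self.r < 1:
            raise ValidationError(f"latent dimension r must be positive, got {self.r}")
        if self.alpha < 0 or self.beta < 0:
            raise ValidationError("alpha and beta must be non-negative")
        if self.max_iter < 0:
            raise ValidationError("max_iter must be >= 0")
        if self.tol <= 0 or self.epsilon <= 0:
            raise ValidationError("tol and epsilon must be positive")


@dataclass
class LatentFactors:
    """Non-negative basis (lincRNAs x r) and feature (r x diseases) matrices."""

    B: np.ndarray
    F: np.ndarray
    rows: Optional[EntityIndex] = None
    cols: Optional[EntityIndex] = None

    def __post_init__(self) -> None:
        self.B = np.asarray(self.B, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        if self.B.ndim != 2 or self.F.ndim != 2 or self.B.shape[1] != self.F.shape[0]:
            raise ValidationError(
                f"factor shapes {self.B.shape} x {self.F.shape} do not conform"
            )
        if np.any(self.B < 0) or np.any(self.F < 0):
            raise ValidationError("latent factors must be non-negative")


@dataclass
class FitResult:
    """Fitted factors plus the objective trajectory of the optimizer."""

    factors: LatentFactors
    objective: List[float]
    iterations: int
    converged: bool


# ---------------------------------------------------------------------------
# model pieces

def path_target(
    z: AssociationMatrix,
    gnet: WeightedNetwork,
    y: AssociationMatrix,
    normalize: bool = False,
) -> AssociationMatrix:
    """Path-weight matrix T = Z'·W·Y (lincRNA x disease).

    Entry (l, d) sums the weights of all lincRNA → gene → gene → disease
    paths: ``T_ld = Σ_k Σ_m z_kl w_km y_md``.  With ``normalize=True`` the
    degree-normalized gene adjacency replaces the raw weights.
    """
    if z.rows.ids != gnet.nodes.ids or y.rows.ids != gnet.nodes.ids:
        raise ValidationError(
            "path target needs z, the gene network and y over an identical "
            "gene index (run align_matrices first)"
        )
    w = build_normalized_laplacian(gnet).adjacency_part if normalize else gnet.weights
    t = z.values.T @ w @ y.values
    return AssociationMatrix(z.cols, y.cols, t)


def _objective_arrays(
    x: np.ndarray,
    b: np.ndarray,
    f: np.ndarray,
    ip: Optional[np.ndarray],
    ap: Optional[np.ndarray],
    t: Optional[np.ndarray],
    alpha: float,
    beta: float,
) -> float:
    bf = b @ f
    resid = x - bf
    val = 0.5 * float(np.sum(resid * resid))
    if alpha != 0.0 and ip is not None:
        lb = ip @ b - ap @ b
        val += alpha * float(np.sum(b * lb))
    if beta != 0.0 and t is not None:
        resid_t = bf - t
        val += 0.5 * beta * float(np.sum(resid_t * resid_t))
    return val


def objective(
    x_hat: AssociationMatrix,
    factors: LatentFactors,
    lap: Optional[NormalizedLaplacian],
    target: Optional[AssociationMatrix],
    config: CrnmfConfig,
) -> float:
    """Evaluate the co-regularized objective at the given factors."""
    ip = lap.identity_part if lap is not None else None
    ap = lap.adjacency_part if lap is not None else None
    t = target.values if target is not None else None
    val = _objective_arrays(
        x_hat.values, factors.B, factors.F, ip, ap, t, config.alpha, config.beta
    )
    if not np.isfinite(val):
        raise NumericalError("objective is non-finite")
    return val


def update_B(
    b: np.ndarray,
    f: np.ndarray,
    x: np.ndarray,
    ip: Optional[np.ndarray],
    ap: Optional[np.ndarray],
    t: Optional[np.ndarray],
    alpha: float,
    beta: float,
    epsilon: float = 1e-12,
) -> np.ndarray:
    """One multiplicative update of the basis matrix.

    B ← B ⊙ [X̂F' + β·T·F' + 2α·W̄·B] ⊘ [(1+β)·B·F·F' + 2α·I_d·B + ε]
    """
    ft = f.T
    num = x @ ft
    den = (1.0 + beta) * (b @ (f @ ft))
    if beta != 0.0 and t is not None:
        num = num + beta * (t @ ft)
    if alpha != 0.0 and ip is not None:
        num = num + 2.0 * alpha * (ap @ b)
        den = den + 2.0 * alpha * (ip @ b)
    return b * num / (den + epsilon)


def update_F(
    b: np.ndarray,
    f: np.ndarray,
    x: np.ndarray,
    t: Optional[np.ndarray],
    beta: float,
    epsilon: float = 1e-12,
) -> np.ndarray:
    """One multiplicative update of the feature matrix.

    F ← F ⊙ [B'X̂ + β·B'·T] ⊘ [(1+β)·B'·B·F + ε]
    """
    bt = b.T
    num = bt @ x
    den = (1.0 + beta) * (bt @ b @ f)
    if beta != 0.0 and t is not None:
        num = num + beta * (bt @ t)
    return f * num / (den + epsilon)


def initialize_factors(
    x: np.ndarray, r: int, seed: int, epsilon: float = 1e-12
) -> Tuple[np.ndarray, np.ndarray]:
    """Seeded i.i.d. uniform(0,1) factors scaled by sqrt(mean(X̂)/r).

    The scaling puts the initial reconstruction on the magnitude of the data
    so the first updates are well-conditioned.
    """
    rng = np.random.default_rng(seed)
    scale = np.sqrt(max(float(x.mean()), epsilon) / r)
    b = rng.uniform(size=(x.shape[0], r)) * scale
    f = rng.uniform(size=(r, x.shape[1])) * scale
    return b, f


def fit(
    x_hat: AssociationMatrix,
    lap: Optional[NormalizedLaplacian] = None,
    target: Optional[AssociationMatrix] = None,
    config: Optional[CrnmfConfig] = None,
) -> FitResult:
    """Fit the co-regularized factorization by alternating updates.

    Stops when the relative objective change drops below ``config.tol`` or
    after ``config.max_iter`` sweeps.  The recorded objective trajectory
    includes the value at initialization (iteration 0) and is non-increasing.
    """
    cfg = config if config is not None else CrnmfConfig()
    x = x_hat.values
    n_l, n_d = x.shape
    if cfg.r > min(n_l, n_d):
        warnings.warn(
            f"latent dimension r={cfg.r} exceeds min(n_l, n_d)="
            f"{min(n_l, n_d)}; the factorization is over-parameterized",
            stacklevel=2,
        )
    if cfg.alpha > 0 and lap is None:
        raise ValidationError("alpha > 0 requires a lincRNA Laplacian")
    if cfg.beta > 0 and target is None:
        raise ValidationError("beta > 0 requires a path-target matrix")
    if lap is not None and len(lap.nodes) != n_l:
        raise ValidationError("Laplacian size does not match the lincRNA set")
    if target is not None and target.values.shape != (n_l, n_d):
        raise ValidationError("path target shape does not match X̂")

    ip = lap.identity_part if lap is not None else None
    ap = lap.adjacency_part if lap is not None else None
    t = target.values if target is not None else None

    b, f = initialize_factors(x, cfg.r, cfg.seed, cfg.epsilon)
    trajectory = [_objective_arrays(x, b, f, ip, ap, t, cfg.alpha, cfg.beta)]
    converged = False
    for it in range(1, cfg.max_iter + 1):
        b = update_B(b, f, x, ip, ap, t, cfg.alpha, cfg.beta, cfg.epsilon)
        f = update_F(b, f, x, t, cfg.beta, cfg.epsilon)
        val = _objective_arrays(x, b, f, ip, ap, t, cfg.alpha, cfg.beta)
        if not np.isfinite(val):
            raise NumericalError(f"objective became non-finite at iteration {it}")
        trajectory.append(val)
        prev = trajectory[-2]
        if abs(prev - val) < cfg.tol * max(abs(prev), cfg.epsilon):
            converged = True
            break
    factors = LatentFactors(b, f, rows=x_hat.rows, cols=x_hat.cols)
    return FitResult(factors, trajectory, len(trajectory) - 1, converged)


def predict(factors: LatentFactors, clip: bool = True) -> AssociationMatrix:
    """Predicted association scores X = B F, clipped to [0, 1] by default.

    Clipping keeps scores on the scale of the binary labels so the mean
    absolute error against them is calibrated; pass ``clip=False`` for the
    raw reconstruction.
    """
    scores = factors.B @ factors.F
    if clip:
        scores = np.clip(scores, 0.0, 1.0)
    if factors.rows is None or factors.cols is None:
        rows = EntityIndex("lincRNA", tuple(f"l{i}" for i in range(scores.shape[0])))
        cols = EntityIndex("disease", tuple(f"d{j}" for j in range(scores.shape[1])))
    else:
        rows, cols = factors.rows, factors.cols
    return AssociationMatrix(rows, cols, scores)


def kkt_residual(
    x_hat: AssociationMatrix,
    factors: LatentFactors,
    lap: Optional[NormalizedLaplacian],
    target: Optional[AssociationMatrix],
    config: CrnmfConfig,
) -> Tuple[float, float]:
    """Max magnitude of min(factor, gradient), element-wise, for B and F.

    Zero at an exact KKT point: wherever a factor entry is positive the
    gradient must vanish, and wherever the gradient is positive the entry
    must be zero.
    """
    b, f, x = factors.B, factors.F, x_hat.values
    t = target.values if target is not None else None
    beta, alpha = config.beta, config.alpha
    grad_b = (1.0 + beta) * (b @ (f @ f.T)) - x @ f.T
    if beta != 0.0 and t is not None:
        grad_b -= beta * (t @ f.T)
    if alpha != 0.0 and lap is not None:
        grad_b += 2.0 * alpha * (lap.matrix @ b)
    grad_f = (1.0 + beta) * (b.T @ b @ f) - b.T @ x
    if beta != 0.0 and t is not None:
        grad_f -= beta * (b.T @ t)
    res_b = float(np.abs(np.minimum(b, grad_b)).max())
    res_f = float(np.abs(np.minimum(f, grad_f)).max())
    return res_b, res_f
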