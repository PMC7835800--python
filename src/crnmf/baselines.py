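"""Baseline predictors defined alongside the co-regularized model:
network label propagation and plain (unregularized) NMF."""

from __future__ import annotations

from dataclasses import replace
from typing import Optional

import numpy as np
import scipy.linalg

from .datatypes import (
    AssociationMatrix,
    NormalizedLaplacian,
    ValidationError,
)
from .factorization import CrnmfConfig, FitResult, fit


def label_propagation(
    x_hat: AssociationMatrix,
    lap: NormalizedLaplacian,
    theta: float = 0.5,
    clip: bool = True,
    method: str = "solve",
    n_steps: int = 500,
) -> AssociationMatrix:
    """Minimize θ·Tr(X'LX) + (1−θ)·||X − X̂||_F² over the co-expression graph.

    The unique minimizer is ``X* = (1−θ)·(θL + (1−θ)I)^{-1}·X̂``; for θ < 1
    the system matrix is positive definite so the direct solve always
    succeeds.  ``method="iterate"`` runs the equivalent convergent fixed
    point ``X ← θ·W̄·X + (1−θ)·X̂`` (rows of isolated nodes pinned to X̂)
    for ``n_steps`` steps instead.  Disease columns decouple, so solving the
    whole matrix at once equals per-disease propagation.
    """
    if not 0.0 < theta < 1.0:
        raise ValidationError(f"theta must lie strictly in (0, 1), got {theta}")
    if lap.nodes.ids != x_hat.rows.ids:
        raise ValidationError("Laplacian and X̂ must share the lincRNA index")
    x = x_hat.values
    n = x.shape[0]
    if method == "solve":
        a = theta * lap.matrix + (1.0 - theta) * np.eye(n)
        scores = (1.0 - theta) * scipy.linalg.solve(a, x, assume_a="pos")
    elif method == "iterate":
        isolated = np.diagonal(lap.identity_part) == 0
        scores = x.copy()
        for _ in range(n_steps):
            scores = theta * (lap.adjacency_part @ scores) + (1.0 - theta) * x
            scores[isolated] = x[isolated]
    else:
        raise ValidationError(f"unknown label-propagation method {method!r}")
    scores = np.clip(scores, 0.0, 1.0) if clip else np.maximum(scores, 0.0)
    return AssociationMatrix(x_hat.rows, x_hat.cols, scores)


def plain_nmf(
    x_hat: AssociationMatrix, config: Optional[CrnmfConfig] = None
) -> FitResult:
    """Classical two-factor NMF of X̂: the co-regularized fit with α = β = 0.

    Exposed under its own name for the benchmark harness; with a shared seed
    the trajectory is identical to ``fit`` at zero regularization.
    """
    cfg = config if config is not None else CrnmfConfig()
    return fit(x_hat, lap=None, target=None, config=replace(cfg, alpha=0.0, beta=0.0))
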