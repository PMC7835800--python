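"""Network construction: the lincRNA co-expression graph, the gene-lincRNA
association matrix, and normalized Laplacians."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import (
    AssociationMatrix,
    EntityIndex,
    NormalizedLaplacian,
    ValidationError,
    WeightedNetwork,
)


def build_coexpression_network(
    expr: pd.DataFrame, threshold: float = 0.5
) -> WeightedNetwork:
    """Build a lincRNA co-expression network from an expression profile.

    Edge weight is ``|Pearson r|`` between the two expression rows when that
    absolute correlation is at least ``threshold``, else 0.  Zero-variance
    rows get no edges; the diagonal is zero.  Weights are invariant to
    positive affine transforms of individual expression rows.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValidationError(f"threshold must lie in [0, 1], got {threshold}")
    values = np.asarray(expr, dtype=float)
    if values.ndim != 2 or values.shape[1] < 2:
        raise ValidationError("co-expression needs at least 2 samples")
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(values)
    corr = np.nan_to_num(corr, nan=0.0)  # zero-variance rows -> no edges
    weights = np.abs(corr)
    np.clip(weights, 0.0, 1.0, out=weights)  # |r| can exceed 1 by rounding
    weights[weights < threshold] = 0.0
    np.fill_diagonal(weights, 0.0)
    weights = (weights + weights.T) / 2.0
    nodes = EntityIndex("lincRNA", tuple(expr.index.astype(str)))
    return WeightedNetwork(nodes, weights)


def build_gene_lincrna_associations(
    y: AssociationMatrix, x: AssociationMatrix
) -> AssociationMatrix:
    """Connect gene i to lincRNA j iff they share at least one disease.

    ``z_ij = 1`` iff there is a disease k with ``y_ik = 1`` and ``x_jk = 1``,
    i.e. the element-wise indicator of ``Y X' > 0``.  Both inputs must carry
    the identical (post-alignment) disease index.
    """
    if x.cols.ids != y.cols.ids:
        raise ValidationError(
            "gene-disease and lincRNA-disease matrices must share an "
            "identical disease index"
        )
    y.require_binary()
    x.require_binary()
    z = (y.values @ x.values.T > 0).astype(float)
    return AssociationMatrix(y.rows, x.rows, z)


def build_normalized_laplacian(net: WeightedNetwork) -> NormalizedLaplacian:
    """Construct L = I_d - D^{-1/2} W D^{-1/2} as two non-negative parts.

    ``d^{-1/2}`` is taken as 0 for zero-degree nodes (pseudo-inverse
    convention), so rows and columns of isolated nodes vanish in both parts
    and isolated entities contribute nothing to the graph regularizer.
    """
    d = net.degree
    with np.errstate(divide="ignore"):
        d_isqrt = np.where(d > 0, 1.0 / np.sqrt(np.where(d > 0, d, 1.0)), 0.0)
    adjacency_part = d_isqrt[:, None] * net.weights * d_isqrt[None, :]
    identity_part = np.diag((d > 0).astype(float))
    return NormalizedLaplacian(net.nodes, identity_part, adjacency_part)
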