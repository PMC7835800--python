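"""Labeled containers for the heterogeneous lincRNA / gene / disease network.

Every matrix in the pipeline carries its entity labels explicitly.  Positions
are an internal detail: files only ever contain string identifiers, and the
order of an :class:`EntityIndex` is stable for the lifetime of a run, so the
same integer always refers to the same entity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

ENTITY_KINDS = ("lincRNA", "gene", "disease")

#: tolerance for the symmetry check on weighted networks
SYMMETRY_TOL = 1e-10


class ValidationError(ValueError):
    """An object violates one of its structural invariants."""


class AlignmentError(ValidationError):
    """Entity sets required to overlap have an empty intersection."""


class ParseError(ValueError):
    """An on-disk file cannot be interpreted."""


class NumericalError(RuntimeError):
    """The optimizer produced non-finite values."""


@dataclass(frozen=True)
class EntityIndex:
    """An ordered, duplicate-free set of entity identifiers of one kind."""

    kind: str
    ids: tuple

    def __post_init__(self) -> None:
        if self.kind not in ENTITY_KINDS:
            raise ValidationError(
                f"unknown entity kind {self.kind!r}; expected one of {ENTITY_KINDS}"
            )
        ids = tuple(str(i) for i in self.ids)
        if not ids:
            raise ValidationError(f"{self.kind} index is empty")
        if any(i == "" for i in ids):
            raise ValidationError(f"{self.kind} index contains an empty identifier")
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if list(ids).count(i) > 1})
            raise ValidationError(f"duplicate {self.kind} identifiers: {dupes[:5]}")
        object.__setattr__(self, "ids", ids)
        object.__setattr__(self, "_pos", {i: k for k, i in enumerate(ids)})

    def __len__(self) -> int:
        return len(self.ids)

    def position(self, entity_id: str) -> int:
        try:
            return self._pos[entity_id]
        except KeyError:
            raise KeyError(f"unknown {self.kind} id {entity_id!r}") from None

    def positions(self, entity_ids: Sequence[str]) -> np.ndarray:
        return np.asarray([self.position(i) for i in entity_ids], dtype=int)


def _check_finite(values: np.ndarray, what: str) -> None:
    if not np.all(np.isfinite(values)):
        raise ValidationError(f"{what} contains non-finite values")


@dataclass
class AssociationMatrix:
    """A labeled matrix of associations between two entity sets.

    Binary for known associations (the observed lincRNA-disease, gene-disease
    and gene-lincRNA matrices), real-valued and non-negative for predicted
    scores.
    """

    rows: EntityIndex
    cols: EntityIndex
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.rows), len(self.cols)):
            raise ValidationError(
                f"association matrix shape {self.values.shape} does not match "
                f"labels ({len(self.rows)} {self.rows.kind} x "
                f"{len(self.cols)} {self.cols.kind})"
            )
        _check_finite(self.values, "association matrix")
        if np.any(self.values < 0):
            raise ValidationError("association matrix has negative entries")

    @property
    def shape(self) -> tuple:
        return self.values.shape

    def is_binary(self) -> bool:
        return bool(np.isin(self.values, (0.0, 1.0)).all())

    def require_binary(self) -> "AssociationMatrix":
        if not self.is_binary():
            raise ValidationError(
                f"{self.rows.kind}-{self.cols.kind} associations must be binary"
            )
        return self

    def copy(self) -> "AssociationMatrix":
        return AssociationMatrix(self.rows, self.cols, self.values.copy())

    def reindex(
        self,
        row_ids: Optional[Sequence[str]] = None,
        col_ids: Optional[Sequence[str]] = None,
    ) -> "AssociationMatrix":
        """Restrict/reorder to the given identifier lists (all must exist)."""
        rows, cols, values = self.rows, self.cols, self.values
        if row_ids is not None:
            values = values[rows.positions(row_ids), :]
            rows = EntityIndex(rows.kind, tuple(row_ids))
        if col_ids is not None:
            values = values[:, cols.positions(col_ids)]
            cols = EntityIndex(cols.kind, tuple(col_ids))
        return AssociationMatrix(rows, cols, values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.rows.ids),
                            columns=list(self.cols.ids))


@dataclass
class WeightedNetwork:
    """A symmetric, non-negative weighted graph over a single entity set."""

    nodes: EntityIndex
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        n = len(self.nodes)
        if self.weights.shape != (n, n):
            raise ValidationError(
                f"network weight matrix shape {self.weights.shape} does not "
                f"match {n} {self.nodes.kind} nodes"
            )
        _check_finite(self.weights, "network weights")
        if np.any(self.weights < 0):
            raise ValidationError("network weights must be non-negative")
        if np.abs(self.weights - self.weights.T).max(initial=0.0) > SYMMETRY_TOL:
            raise ValidationError("network weight matrix is not symmetric")
        if np.abs(np.diagonal(self.weights)).max(initial=0.0) > 0:
            raise ValidationError("network has nonzero diagonal (self-loops)")

    @property
    def degree(self) -> np.ndarray:
        """Weighted degree d_i = sum_j w_ij."""
        return self.weights.sum(axis=1)

    def reindex(self, node_ids: Sequence[str]) -> "WeightedNetwork":
        pos = self.nodes.positions(node_ids)
        return WeightedNetwork(
            EntityIndex(self.nodes.kind, tuple(node_ids)),
            self.weights[np.ix_(pos, pos)],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.weights, index=list(self.nodes.ids),
                            columns=list(self.nodes.ids))


@dataclass
class NormalizedLaplacian:
    """The normalized graph Laplacian L = I_d - D^{-1/2} W D^{-1/2}.

    Stored as two non-negative parts because the multiplicative update must
    separate positive and negative gradient contributions: ``identity_part``
    is the identity restricted to nonzero-degree nodes, ``adjacency_part`` is
    the degree-normalized adjacency.  Rows/columns of isolated nodes are zero
    in both parts (pseudo-inverse convention for D^{-1/2}).
    """

    nodes: EntityIndex
    identity_part: np.ndarray
    adjacency_part: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.nodes)
        self.identity_part = np.asarray(self.identity_part, dtype=float)
        self.adjacency_part = np.asarray(self.adjacency_part, dtype=float)
        for name, m in (("identity_part", self.identity_part),
                        ("adjacency_part", self.adjacency_part)):
            if m.shape != (n, n):
                raise ValidationError(f"{name} shape {m.shape} != ({n}, {n})")
            _check_finite(m, name)
        if np.any(self.adjacency_part < 0):
            raise ValidationError("adjacency_part must be non-negative")

    @property
    def matrix(self) -> np.ndarray:
        """The Laplacian L = identity_part - adjacency_part."""
        return self.identity_part - self.adjacency_part


@dataclass
class DataBundle:
    """The five inputs of the heterogeneous-network pipeline.

    x : lincRNA x disease known associations (binary)
    y : gene x disease known associations (binary)
    z : gene x lincRNA associations (binary)
    gene_net : gene genetic-interaction network
    expression : lincRNA x sample expression profile (optional if
        ``lincrna_net`` is given directly)
    lincrna_net : lincRNA co-expression network (optional; built from
        ``expression`` when absent)
    """

    x: AssociationMatrix
    y: AssociationMatrix
    z: AssociationMatrix
    gene_net: WeightedNetwork
    expression: Optional[pd.DataFrame] = None
    lincrna_net: Optional[WeightedNetwork] = None

    def __post_init__(self) -> None:
        if self.expression is None and self.lincrna_net is None:
            raise ValidationError(
                "bundle needs either a lincRNA expression profile or a "
                "co-expression network"
            )
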