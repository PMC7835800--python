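"""Readers and writers for the on-disk TSV formats.

Three formats are supported:

* **pair lists** — two or three tab-separated columns ``rowId colId [weight]``
  for known (binary) associations;
* **edge lists** — ``idA idB weight`` for weighted networks;
* **labeled matrices** — a header row of column ids and a first column of row
  ids, used for expression profiles, fitted factors, predicted scores and for
  lossless round-trips of whole matrices (pair/edge lists cannot represent
  all-zero rows or isolated nodes).

Lines starting with ``#`` are comments.  Files carry string identifiers only,
never positions.
"""

from __future__ import annotations

import os
from typing import Tuple

import numpy as np
import pandas as pd
import yaml

from .datatypes import (
    AlignmentError,
    AssociationMatrix,
    DataBundle,
    EntityIndex,
    ParseError,
    ValidationError,
    WeightedNetwork,
)


def _data_lines(path):
    """Yield (line_number, stripped_line) skipping blanks and comments."""
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line


def read_association_pairs(path, row_kind: str, col_kind: str) -> AssociationMatrix:
    """Read a binary association matrix from a TSV pair list.

    Duplicate pairs collapse to a single 1; identifiers are sorted
    lexicographically so the result is independent of file order.
    """
    pairs = set()
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) not in (2, 3):
            raise ParseError(
                f"{path}: line {lineno}: expected 2-3 tab-separated fields, "
                f"got {len(fields)}"
            )
        pairs.add((fields[0], fields[1]))
    if not pairs:
        raise ParseError(f"{path}: no association pairs found")
    row_ids = sorted({r for r, _ in pairs})
    col_ids = sorted({c for _, c in pairs})
    rows = EntityIndex(row_kind, tuple(row_ids))
    cols = EntityIndex(col_kind, tuple(col_ids))
    values = np.zeros((len(rows), len(cols)))
    for r, c in pairs:
        values[rows.position(r), cols.position(c)] = 1.0
    return AssociationMatrix(rows, cols, values)


def write_association_pairs(am: AssociationMatrix, path) -> None:
    am.require_binary()
    with open(path, "w", encoding="utf-8") as fh:
        for i, j in zip(*np.nonzero(am.values)):
            fh.write(f"{am.rows.ids[i]}\t{am.cols.ids[j]}\n")


def read_edge_list(path, kind: str) -> WeightedNetwork:
    """Read a symmetric weighted network from a TSV edge list.

    Edges listed once are mirrored; conflicting duplicate weights resolve to
    the maximum; self-loops are dropped (their nodes are kept).
    """
    edges = {}
    node_ids = set()
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) != 3:
            raise ParseError(
                f"{path}: line {lineno}: expected 3 tab-separated fields "
                f"(idA, idB, weight), got {len(fields)}"
            )
        a, b, w_str = fields
        try:
            w = float(w_str)
        except ValueError:
            raise ParseError(
                f"{path}: line {lineno}: weight {w_str!r} is not numeric"
            ) from None
        if not np.isfinite(w) or w < 0:
            raise ValidationError(
                f"{path}: line {lineno}: weight must be finite and "
                f"non-negative, got {w_str}"
            )
        node_ids.update((a, b))
        if a == b:
            continue
        key = (a, b) if a < b else (b, a)
        edges[key] = max(edges.get(key, 0.0), w)
    if not node_ids:
        raise ParseError(f"{path}: no edges found")
    nodes = EntityIndex(kind, tuple(sorted(node_ids)))
    weights = np.zeros((len(nodes), len(nodes)))
    for (a, b), w in edges.items():
        i, j = nodes.position(a), nodes.position(b)
        weights[i, j] = weights[j, i] = w
    return WeightedNetwork(nodes, weights)


def write_edge_list(net: WeightedNetwork, path) -> None:
    iu, ju = np.triu_indices(len(net.nodes), k=1)
    with open(path, "w", encoding="utf-8") as fh:
        for i, j in zip(iu, ju):
            w = net.weights[i, j]
            if w != 0:
                fh.write(f"{net.nodes.ids[i]}\t{net.nodes.ids[j]}\t{float(w)!r}\n")


def _read_table(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#",
                         float_precision="round_trip")
    except FileNotFoundError:
        raise
    except Exception as exc:  # pandas raises several parser error types
        raise ParseError(f"{path}: cannot parse labeled matrix: {exc}") from exc
    if df.index.has_duplicates:
        dupes = sorted(df.index[df.index.duplicated()].unique().tolist())
        raise ValidationError(f"{path}: duplicate row identifiers: {dupes[:5]}")
    if df.columns.has_duplicates:
        raise ValidationError(f"{path}: duplicate column names")
    bad = df.isna().any(axis=1)
    if bad.any():
        raise ParseError(
            f"{path}: missing or non-numeric cell in row {df.index[bad][0]!r}"
        )
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric cell: {exc}") from exc
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def read_expression_matrix(path, kind: str) -> pd.DataFrame:
    """Read an entities x samples expression profile (entity order preserved)."""
    if kind not in ("lincRNA", "gene"):
        raise ValidationError(f"expression matrices hold lincRNAs or genes, not {kind!r}")
    df = _read_table(path)
    if df.shape[1] < 1:
        raise ParseError(f"{path}: expression matrix has no sample columns")
    return df


def read_labeled_matrix(path, row_kind: str, col_kind: str) -> AssociationMatrix:
    df = _read_table(path)
    return AssociationMatrix(
        EntityIndex(row_kind, tuple(df.index)),
        EntityIndex(col_kind, tuple(df.columns)),
        df.to_numpy(),
    )


def read_labeled_network(path, kind: str) -> WeightedNetwork:
    df = _read_table(path)
    if list(df.index) != list(df.columns):
        raise ValidationError(f"{path}: network matrix rows and columns differ")
    return WeightedNetwork(EntityIndex(kind, tuple(df.index)), df.to_numpy())


def write_labeled_matrix(obj, path) -> None:
    """Write an AssociationMatrix / WeightedNetwork / DataFrame as labeled TSV."""
    df = obj if isinstance(obj, pd.DataFrame) else obj.to_frame()
    df.to_csv(path, sep="\t", float_format="%.17g")


def align_matrices(
    x: AssociationMatrix,
    y: AssociationMatrix,
    z: AssociationMatrix,
    gnet: WeightedNetwork,
    lnet: WeightedNetwork,
) -> Tuple[AssociationMatrix, AssociationMatrix, AssociationMatrix,
           WeightedNetwork, WeightedNetwork]:
    """Reindex the five inputs to shared, lexicographically sorted id lists.

    lincRNAs = x.rows ∩ lnet.nodes ∩ z.cols; genes = y.rows ∩ gnet.nodes ∩
    z.rows; diseases = x.cols ∩ y.cols.  Entities present in only some
    sources are dropped (intersection semantics), after which the matrix
    products Z'·W·Y and B·F are conformable.
    """
    _expect_kinds(x, "lincRNA", "disease")
    _expect_kinds(y, "gene", "disease")
    _expect_kinds(z, "gene", "lincRNA")
    if gnet.nodes.kind != "gene" or lnet.nodes.kind != "lincRNA":
        raise ValidationError("networks must be over genes and lincRNAs")
    lincs = sorted(set(x.rows.ids) & set(lnet.nodes.ids) & set(z.cols.ids))
    genes = sorted(set(y.rows.ids) & set(gnet.nodes.ids) & set(z.rows.ids))
    diseases = sorted(set(x.cols.ids) & set(y.cols.ids))
    for kind, ids in (("lincRNA", lincs), ("gene", genes), ("disease", diseases)):
        if not ids:
            raise AlignmentError(f"empty {kind} intersection across inputs")
    return (
        x.reindex(lincs, diseases),
        y.reindex(genes, diseases),
        z.reindex(genes, lincs),
        gnet.reindex(genes),
        lnet.reindex(lincs),
    )


def _expect_kinds(am: AssociationMatrix, row_kind: str, col_kind: str) -> None:
    if am.rows.kind != row_kind or am.cols.kind != col_kind:
        raise ValidationError(
            f"expected a {row_kind} x {col_kind} matrix, got "
            f"{am.rows.kind} x {am.cols.kind}"
        )


# ---------------------------------------------------------------------------
# bundle and fit-result round trips (labeled-matrix format, lossless)

def save_bundle(bundle: DataBundle, outdir) -> None:
    os.makedirs(outdir, exist_ok=True)
    write_labeled_matrix(bundle.x, os.path.join(outdir, "x.tsv"))
    write_labeled_matrix(bundle.y, os.path.join(outdir, "y.tsv"))
    write_labeled_matrix(bundle.z, os.path.join(outdir, "z.tsv"))
    write_labeled_matrix(bundle.gene_net, os.path.join(outdir, "gene_net.tsv"))
    if bundle.expression is not None:
        write_labeled_matrix(bundle.expression, os.path.join(outdir, "expression.tsv"))
    if bundle.lincrna_net is not None:
        write_labeled_matrix(bundle.lincrna_net, os.path.join(outdir, "lincrna_net.tsv"))


def load_bundle(indir) -> DataBundle:
    p = lambda name: os.path.join(indir, name)
    expression = None
    if os.path.exists(p("expression.tsv")):
        expression = read_expression_matrix(p("expression.tsv"), "lincRNA")
    lincrna_net = None
    if os.path.exists(p("lincrna_net.tsv")):
        lincrna_net = read_labeled_network(p("lincrna_net.tsv"), "lincRNA")
    return DataBundle(
        x=read_labeled_matrix(p("x.tsv"), "lincRNA", "disease"),
        y=read_labeled_matrix(p("y.tsv"), "gene", "disease"),
        z=read_labeled_matrix(p("z.tsv"), "gene", "lincRNA"),
        gene_net=read_labeled_network(p("gene_net.tsv"), "gene"),
        expression=expression,
        lincrna_net=lincrna_net,
    )


def save_fit_result(result, outdir, config=None) -> None:
    """Write B.tsv, F.tsv, objective.tsv and meta.yaml for a FitResult."""
    os.makedirs(outdir, exist_ok=True)
    factors = result.factors
    r = factors.B.shape[1]
    latent = [f"f{k + 1}" for k in range(r)]
    row_ids = list(factors.rows.ids) if factors.rows is not None else \
        [f"row{i}" for i in range(factors.B.shape[0])]
    col_ids = list(factors.cols.ids) if factors.cols is not None else \
        [f"col{j}" for j in range(factors.F.shape[1])]
    pd.DataFrame(factors.B, index=row_ids, columns=latent).to_csv(
        os.path.join(outdir, "B.tsv"), sep="\t", float_format="%.17g")
    pd.DataFrame(factors.F, index=latent, columns=col_ids).to_csv(
        os.path.join(outdir, "F.tsv"), sep="\t", float_format="%.17g")
    pd.DataFrame({"iteration": range(len(result.objective)),
                  "objective": result.objective}).to_csv(
        os.path.join(outdir, "objective.tsv"), sep="\t", index=False)
    meta = {"iterations": int(result.iterations),
            "converged": bool(result.converged),
            "final_objective": float(result.objective[-1])}
    if config is not None:
        meta["config"] = {k: (v if not isinstance(v, np.generic) else v.item())
                          for k, v in vars(config).items()}
    with open(os.path.join(outdir, "meta.yaml"), "w", encoding="utf-8") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)


def load_factors(indir):
    """Read B.tsv / F.tsv back into a LatentFactors object."""
    from .factorization import LatentFactors

    b = _read_table(os.path.join(indir, "B.tsv"))
    f = _read_table(os.path.join(indir, "F.tsv"))
    return LatentFactors(
        B=b.to_numpy(),
        F=f.to_numpy(),
        rows=EntityIndex("lincRNA", tuple(b.index)),
        cols=EntityIndex("disease", tuple(f.columns)),
    )
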