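"""Metrics, cross-validation protocols and parameter-sweep drivers.

Accuracy is defined on the score scale, ``Accuracy = 1 − MAE``, where MAE is
the mean absolute difference between observed labels and predicted scores
over the test cells τ.  RMSE is the root mean squared error over τ; RSS is
the residual sum of squares over *all* cells of the matrix (used for model
selection on the training reconstruction).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace
from typing import Callable, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .baselines import label_propagation, plain_nmf
from .datatypes import (
    AssociationMatrix,
    DataBundle,
    NormalizedLaplacian,
    ValidationError,
)
from .factorization import CrnmfConfig, fit, path_target, predict
from .networks import build_coexpression_network, build_normalized_laplacian

MethodType = Union[str, AssociationMatrix, Callable[[AssociationMatrix], AssociationMatrix]]

METHOD_IDS = ("crnmf", "nmf", "lp", "constant")


@dataclass(frozen=True)
class TestMask:
    """The set τ of held-out (lincRNA, disease) positions."""

    __test__ = False  # not a pytest class, despite the name

    pairs: tuple

    def __post_init__(self) -> None:
        pairs = tuple(sorted({(int(i), int(j)) for i, j in self.pairs}))
        if not pairs:
            raise ValidationError("test mask is empty")
        object.__setattr__(self, "pairs", pairs)

    @classmethod
    def from_column(cls, col: int, n_rows: int) -> "TestMask":
        return cls(tuple((i, col) for i in range(n_rows)))

    def indices(self) -> Tuple[np.ndarray, np.ndarray]:
        arr = np.asarray(self.pairs, dtype=int)
        return arr[:, 0], arr[:, 1]

    def check_bounds(self, shape: Tuple[int, int]) -> None:
        rows, cols = self.indices()
        if rows.min() < 0 or cols.min() < 0 or rows.max() >= shape[0] or cols.max() >= shape[1]:
            raise ValidationError(f"test mask positions fall outside matrix shape {shape}")

    def __len__(self) -> int:
        return len(self.pairs)


def _values(m) -> np.ndarray:
    return m.values if isinstance(m, AssociationMatrix) else np.asarray(m, dtype=float)


def mae(observed, predicted, mask: TestMask) -> float:
    """Mean absolute difference over the test cells τ."""
    obs, pred = _values(observed), _values(predicted)
    mask.check_bounds(obs.shape)
    rows, cols = mask.indices()
    return float(np.mean(np.abs(obs[rows, cols] - pred[rows, cols])))


def accuracy(observed, predicted, mask: TestMask) -> float:
    """Exactly 1 − MAE."""
    return 1.0 - mae(observed, predicted, mask)


def rmse(observed, predicted, mask: TestMask) -> float:
    """Root mean squared error over the test cells τ."""
    obs, pred = _values(observed), _values(predicted)
    mask.check_bounds(obs.shape)
    rows, cols = mask.indices()
    return float(np.sqrt(np.mean((obs[rows, cols] - pred[rows, cols]) ** 2)))


def rss(observed, predicted) -> float:
    """Residual sum of squares over all cells (no τ restriction)."""
    diff = _values(observed) - _values(predicted)
    return float(np.sum(diff * diff))


@dataclass
class EvaluationReport:
    """Per-fold and aggregate metrics for one evaluation protocol."""

    per_fold: pd.DataFrame
    aggregate: dict
    rss: Optional[float] = None

    def save(self, outdir) -> None:
        os.makedirs(outdir, exist_ok=True)
        self.per_fold.to_csv(os.path.join(outdir, "per_fold.tsv"), sep="\t", index=False)
        agg = dict(self.aggregate)
        if self.rss is not None:
            agg["rss"] = self.rss
        pd.DataFrame([agg]).to_csv(os.path.join(outdir, "aggregate.tsv"),
                                   sep="\t", index=False)


def prepare_bundle(
    bundle: DataBundle,
    threshold: float = 0.5,
    normalize_gene_net: bool = False,
) -> Tuple[NormalizedLaplacian, AssociationMatrix]:
    """Build the lincRNA Laplacian and the path-target matrix for a bundle."""
    lnet = bundle.lincrna_net
    if lnet is None:
        lnet = build_coexpression_network(bundle.expression, threshold)
    lap = build_normalized_laplacian(lnet)
    target = path_target(bundle.z, bundle.gene_net, bundle.y,
                         normalize=normalize_gene_net)
    return lap, target


def _score(
    method: MethodType,
    train: AssociationMatrix,
    lap: NormalizedLaplacian,
    target: AssociationMatrix,
    config: CrnmfConfig,
    theta: float,
    seed: int,
) -> AssociationMatrix:
    if callable(method):
        return method(train)
    if isinstance(method, AssociationMatrix):  # externally supplied scores
        return method
    if method == "crnmf":
        res = fit(train, lap, target, replace(config, seed=seed))
        return predict(res.factors, clip=config.clip_predictions)
    if method == "nmf":
        res = plain_nmf(train, replace(config, seed=seed))
        return predict(res.factors, clip=config.clip_predictions)
    if method == "lp":
        return label_propagation(train, lap, theta=theta)
    if method == "constant":
        return AssociationMatrix(train.rows, train.cols,
                                 np.full(train.shape, 0.5))
    raise ValidationError(f"unknown method {method!r}; expected one of {METHOD_IDS}")


def _aggregate(records: List[dict]) -> dict:
    frame = pd.DataFrame.from_records(records)
    acc = frame["accuracy"].to_numpy()
    sizes = frame["n_cells"].to_numpy()
    return {
        "accuracy_mean": float(acc.mean()),
        "accuracy_sd": float(acc.std(ddof=1)) if len(acc) > 1 else 0.0,
        # per-cell average: folds weighted by |τ| (equals the fold mean when
        # all folds have the same size, e.g. whole disease columns)
        "accuracy_cell_mean": float(np.average(acc, weights=sizes)),
        "mae_mean": float(frame["mae"].mean()),
        "rmse_mean": float(frame["rmse"].mean()),
        "n_folds": int(len(frame)),
    }


def leave_one_disease_out(
    bundle: DataBundle,
    method: MethodType = "crnmf",
    config: Optional[CrnmfConfig] = None,
    repeats: int = 50,
    theta: float = 0.5,
    threshold: float = 0.5,
    seeds: Optional[Sequence[int]] = None,
    per_cell: bool = False,
) -> EvaluationReport:
    """Leave-one-disease-out cross-validation.

    For each disease, every association in its column is removed from the
    training matrix, the method is refit, and the held-out column (all its
    cells, both classes) is scored; the protocol is repeated ``repeats``
    times with fresh seeds and accuracy is aggregated as mean ± sd over all
    folds and repeats.  ``per_cell=True`` switches to leave-one-positive-out
    granularity instead (one fold per known association).
    """
    if repeats < 1:
        raise ValidationError("repeats must be >= 1")
    cfg = config if config is not None else CrnmfConfig()
    lap, target = prepare_bundle(bundle, threshold, cfg.normalize_gene_net)
    x = bundle.x
    n_l, n_d = x.shape

    if per_cell:
        folds = [((int(i), int(j)), TestMask(((int(i), int(j)),)))
                 for i, j in zip(*np.nonzero(x.values))]
    else:
        folds = [(d, TestMask.from_column(d, n_l)) for d in range(n_d)]

    if seeds is None:
        seeds = [cfg.seed + rep for rep in range(repeats)]
    elif len(seeds) != repeats:
        raise ValidationError("need exactly one seed per repeat")

    records = []
    for rep, seed in enumerate(seeds):
        for fold_id, mask in folds:
            train = x.copy()
            rows, cols = mask.indices()
            train.values[rows, cols] = 0.0
            scores = _score(method, train, lap, target, cfg, theta, int(seed))
            fold_mae = mae(x, scores, mask)
            records.append({
                "fold": fold_id, "repeat": rep, "seed": int(seed),
                "mae": fold_mae, "accuracy": 1.0 - fold_mae,
                "rmse": rmse(x, scores, mask), "n_cells": len(mask),
            })
    return EvaluationReport(pd.DataFrame.from_records(records), _aggregate(records))


def external_validation(
    bundle: DataBundle,
    train: AssociationMatrix,
    test_mask: TestMask,
    method: MethodType = "crnmf",
    config: Optional[CrnmfConfig] = None,
    theta: float = 0.5,
    threshold: float = 0.5,
) -> EvaluationReport:
    """Single-fold validation on associations discovered after the cut-off.

    ``train`` holds the early associations; ``test_mask`` marks cells whose
    associations were reported later (observed value 1).  Any overlap
    between training positives and test cells is leakage and is rejected.
    """
    cfg = config if config is not None else CrnmfConfig()
    test_mask.check_bounds(train.shape)
    rows, cols = test_mask.indices()
    if np.any(train.values[rows, cols] > 0):
        raise ValidationError(
            "test cells overlap training positives (information leakage)"
        )
    lap, target = prepare_bundle(bundle, threshold, cfg.normalize_gene_net)
    observed = train.values.copy()
    observed[rows, cols] = 1.0
    scores = _score(method, train, lap, target, cfg, theta, cfg.seed)
    fold_mae = mae(observed, scores, test_mask)
    record = {
        "fold": 0, "repeat": 0, "seed": cfg.seed, "mae": fold_mae,
        "accuracy": 1.0 - fold_mae,
        "rmse": rmse(observed, scores, test_mask), "n_cells": len(test_mask),
    }
    return EvaluationReport(pd.DataFrame.from_records([record]),
                            _aggregate([record]))


SWEEP_PARAMS = ("r", "alpha_beta", "iterations")


def sweep(
    parameter: str,
    grid: Iterable,
    bundle: DataBundle,
    config: Optional[CrnmfConfig] = None,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Refit over a grid of one hyper-parameter and record RSS / MAE / RMSE.

    ``parameter`` is one of ``r`` (latent dimension), ``alpha_beta`` (sets
    α = β jointly, mirroring the equal-importance assumption), or
    ``iterations`` (optimizer budget).  Metrics are computed on the full
    training reconstruction; the table is plot-ready TSV material.
    """
    if parameter not in SWEEP_PARAMS:
        raise ValidationError(
            f"unknown sweep parameter {parameter!r}; expected one of {SWEEP_PARAMS}"
        )
    cfg = config if config is not None else CrnmfConfig()
    lap, target = prepare_bundle(bundle, threshold, cfg.normalize_gene_net)
    all_cells = TestMask(tuple(
        (i, j) for i in range(bundle.x.shape[0]) for j in range(bundle.x.shape[1])
    ))
    rows = []
    for value in grid:
        if parameter == "r":
            cfg_v = replace(cfg, r=int(value))
        elif parameter == "alpha_beta":
            cfg_v = replace(cfg, alpha=float(value), beta=float(value))
        else:
            cfg_v = replace(cfg, max_iter=int(value))
        res = fit(bundle.x, lap, target, cfg_v)
        scores = predict(res.factors, clip=cfg.clip_predictions)
        rows.append({
            "value": value,
            "rss": rss(bundle.x, scores),
            "mae": mae(bundle.x, scores, all_cells),
            "rmse": rmse(bundle.x, scores, all_cells),
            "iterations": res.iterations,
            "final_objective": res.objective[-1],
        })
    return pd.DataFrame(rows)
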