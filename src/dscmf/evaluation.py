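"""Evaluation protocol: ROC/AUC, repeated ten-fold pair cross-validation,
hyperparameter grid search, and WKNKN sensitivity sweeps.

Pair CV ("CV-p") partitions the known 1-entries of the association matrix
into folds. For each fold the held-out positives are zeroed in the training
matrix, the full pipeline (per-fold GIP kernels, fusion, WKNKN, factorization)
is re-run on the training matrix, and the fold AUC compares the scores of the
masked positives against all unknown (0) pairs of the original matrix. GIP
kernels and WKNKN are recomputed inside every fold so no information about
held-out positives leaks into training; precomputed expression/semantic
similarities are fold-independent side information.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve

from .datatypes import AssociationMatrix, SimilarityMatrix
from .factorization import DscmfConfig, fit, predict
from .similarity import FusionParams, GipParams, fuse, gip_kernel
from .wknkn import WknknParams, wknkn

__all__ = [
    "PipelineParams",
    "CVConfig",
    "CVResult",
    "roc_auc",
    "partition_positive_pairs",
    "cv_pairs",
    "grid_search",
    "default_grid",
    "wknkn_sensitivity",
]

LambdaTriple = tuple[float, float, float]

#: published search grids: lambda_h over powers of two, side weights over
#: decades including zero
LAMBDA_H_GRID = (0.25, 0.5, 1.0, 2.0)
LAMBDA_SIDE_GRID = (0.0, 1e-4, 1e-3, 1e-2, 1e-1)


def default_grid() -> list[LambdaTriple]:
    """Joint grid over (lambda_h, lambda_l, lambda_d): 4 x 5 x 5 triples."""
    return [
        (h, l, d)
        for h, l, d in itertools.product(LAMBDA_H_GRID, LAMBDA_SIDE_GRID,
                                         LAMBDA_SIDE_GRID)
    ]


@dataclass(frozen=True)
class PipelineParams:
    """Everything needed to turn a training matrix into a score matrix."""

    fit_cfg: DscmfConfig = DscmfConfig()
    variant: str = "dscmf"
    gip: GipParams = GipParams()
    fusion: FusionParams = FusionParams()
    wknkn_params: WknknParams | None = WknknParams()
    gip_global: bool = False


@dataclass(frozen=True)
class CVConfig:
    n_folds: int = 10
    n_repeats: int = 30
    mask_mode: str = "pair"
    seed: int = 0
    grid: tuple[LambdaTriple, ...] | None = None
    inner_selection: str = "fixed"
    inner_folds: int = 3

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if self.mask_mode != "pair":
            raise ValueError("only pair masking is supported")
        if self.inner_selection not in ("fixed", "inner_cv"):
            raise ValueError("inner_selection must be 'fixed' or 'inner_cv'")


@dataclass
class CVResult:
    per_repeat_auc: list[float]
    mean_auc: float
    std_auc: float
    chosen_params: list[LambdaTriple]
    roc_points: list[list[list[tuple[float, float]]]]
    per_fold_auc: list[list[float]] = field(default_factory=list)
    fold_test_pairs: list[list[np.ndarray]] = field(default_factory=list)

    def as_frame(self) -> pd.DataFrame:
        rows = []
        for r, fold_aucs in enumerate(self.per_fold_auc):
            lh, ll, ld = self.chosen_params[r]
            for f, auc in enumerate(fold_aucs):
                rows.append(
                    {"repeat": r, "fold": f, "auc": auc,
                     "lambda_h": lh, "lambda_l": ll, "lambda_d": ld}
                )
        return pd.DataFrame(rows)


def roc_auc(scores, labels) -> tuple[float, list[tuple[float, float]]]:
    """AUC by threshold sweep, with the ROC polyline.

    Ties contribute 1/2, so the trapezoidal area equals the normalized
    Mann-Whitney U statistic. Requires both classes present.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel().astype(int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    if labels.min() == labels.max():
        raise ValueError("ROC needs at least one positive and one negative label")
    fpr, tpr, _ = roc_curve(labels, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return auc, list(zip(fpr.tolist(), tpr.tolist()))


def partition_positive_pairs(
    Y: AssociationMatrix, n_folds: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Randomly partition the indices of known 1-entries into folds.

    Each fold is a (m_f, 2) array of (row, col) indices; every positive
    appears in exactly one fold and every fold is nonempty.
    """
    pos = np.argwhere(Y.values == 1)
    if len(pos) < n_folds:
        raise ValueError(
            f"{len(pos)} known positives cannot fill {n_folds} folds"
        )
    perm = rng.permutation(len(pos))
    return [pos[chunk] for chunk in np.array_split(perm, n_folds)]


def _fold_kernels(
    train: AssociationMatrix,
    full: AssociationMatrix,
    sim_l: SimilarityMatrix | None,
    sim_d: SimilarityMatrix | None,
    pp: PipelineParams,
) -> tuple[SimilarityMatrix, SimilarityMatrix]:
    gip_source = full if pp.gip_global else train
    gl = gip_kernel(gip_source, "lncrna", pp.gip)
    gd = gip_kernel(gip_source, "disease", pp.gip)
    Kl = fuse(sim_l, gl, pp.fusion) if sim_l is not None else gl
    Kd = fuse(sim_d, gd, pp.fusion) if sim_d is not None else gd
    return Kl, Kd


def _score_training_matrix(
    train: AssociationMatrix,
    full: AssociationMatrix,
    sim_l: SimilarityMatrix | None,
    sim_d: SimilarityMatrix | None,
    pp: PipelineParams,
    lambdas: LambdaTriple,
) -> np.ndarray:
    """Run kernels -> WKNKN -> factorization on one training matrix."""
    Kl, Kd = _fold_kernels(train, full, sim_l, sim_d, pp)
    fit_input = train
    if pp.wknkn_params is not None:
        fit_input = wknkn(train, Kl, Kd, pp.wknkn_params)
    lh, ll, ld = lambdas
    cfg = replace(pp.fit_cfg, lambda_h=lh, lambda_l=ll, lambda_d=ld)
    result = fit(fit_input, Kl, Kd, cfg, pp.variant)
    return predict(result.factors)


def _one_round(
    Y: AssociationMatrix,
    folds: list[np.ndarray],
    sim_l: SimilarityMatrix | None,
    sim_d: SimilarityMatrix | None,
    pp: PipelineParams,
    lambdas: LambdaTriple,
    collect_roc: bool = True,
) -> tuple[list[float], list[list[tuple[float, float]]]]:
    """Evaluate every fold of one partition with a fixed lambda triple."""
    neg_mask = Y.values == 0
    aucs: list[float] = []
    rocs: list[list[tuple[float, float]]] = []
    for test_pairs in folds:
        train = Y.copy()
        train.values[test_pairs[:, 0], test_pairs[:, 1]] = 0.0
        scores = _score_training_matrix(train, Y, sim_l, sim_d, pp, lambdas)
        pos_scores = scores[test_pairs[:, 0], test_pairs[:, 1]]
        neg_scores = scores[neg_mask]
        s = np.concatenate([pos_scores, neg_scores])
        y = np.concatenate([np.ones(len(pos_scores)), np.zeros(len(neg_scores))])
        auc, points = roc_auc(s, y)
        aucs.append(auc)
        rocs.append(points if collect_roc else [])
    return aucs, rocs


def grid_search(
    Y: AssociationMatrix,
    sim_l: SimilarityMatrix | None = None,
    sim_d: SimilarityMatrix | None = None,
    pipeline: PipelineParams = PipelineParams(),
    grid: list[LambdaTriple] | None = None,
    n_folds: int = 3,
    seed: int = 0,
) -> tuple[LambdaTriple, pd.DataFrame]:
    """Exhaustive lambda-triple search scored by mean pair-CV AUC.

    Ties break toward the smaller ``lambda_l + lambda_d``, then the smaller
    ``lambda_h`` (prefer the least regularized-toward-side-information model
    among equals). Returns the winning triple and the full score table.
    """
    triples = list(grid) if grid is not None else default_grid()
    if not triples:
        raise ValueError("grid must be nonempty")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0x6D)))
    folds = partition_positive_pairs(Y, n_folds, rng)
    rows = []
    for triple in triples:
        aucs, _ = _one_round(Y, folds, sim_l, sim_d, pipeline, triple,
                             collect_roc=False)
        rows.append(
            {"lambda_h": triple[0], "lambda_l": triple[1],
             "lambda_d": triple[2], "mean_auc": float(np.mean(aucs))}
        )
    table = pd.DataFrame(rows)
    best_idx = min(
        range(len(triples)),
        key=lambda i: (
            -rows[i]["mean_auc"],
            triples[i][1] + triples[i][2],
            triples[i][0],
        ),
    )
    return triples[best_idx], table


def cv_pairs(
    Y: AssociationMatrix,
    cfg: CVConfig = CVConfig(),
    pipeline: PipelineParams = PipelineParams(),
    sim_l: SimilarityMatrix | None = None,
    sim_d: SimilarityMatrix | None = None,
) -> CVResult:
    """Repeated n-fold pair cross-validation of the full pipeline.

    With ``inner_selection='inner_cv'`` the lambda triple is re-selected once
    per repeat by an inner ``cfg.inner_folds``-fold grid search (over
    ``cfg.grid``, or the published default grid); with ``'fixed'`` the
    pipeline's configured lambdas are used as-is. Identical seeds give
    bit-identical results.
    """
    if not Y.is_binary:
        raise ValueError("pair CV requires a binary association matrix")
    fixed_triple: LambdaTriple = (
        pipeline.fit_cfg.lambda_h,
        pipeline.fit_cfg.lambda_l,
        pipeline.fit_cfg.lambda_d,
    )
    per_repeat: list[float] = []
    chosen: list[LambdaTriple] = []
    all_rocs: list[list[list[tuple[float, float]]]] = []
    per_fold: list[list[float]] = []
    fold_pairs: list[list[np.ndarray]] = []
    for r in range(cfg.n_repeats):
        rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, r)))
        folds = partition_positive_pairs(Y, cfg.n_folds, rng)
        if cfg.inner_selection == "inner_cv":
            triple, _ = grid_search(
                Y, sim_l, sim_d, pipeline,
                grid=list(cfg.grid) if cfg.grid is not None else None,
                n_folds=cfg.inner_folds,
                seed=int(rng.integers(2**31)),
            )
        else:
            triple = fixed_triple
        aucs, rocs = _one_round(Y, folds, sim_l, sim_d, pipeline, triple)
        per_repeat.append(float(np.mean(aucs)))
        per_fold.append(aucs)
        chosen.append(triple)
        all_rocs.append(rocs)
        fold_pairs.append(folds)
    mean = float(np.mean(per_repeat))
    std = float(np.std(per_repeat, ddof=1)) if len(per_repeat) > 1 else 0.0
    return CVResult(per_repeat, mean, std, chosen, all_rocs, per_fold, fold_pairs)


def wknkn_sensitivity(
    Y: AssociationMatrix,
    K_values,
    P_values,
    cfg: CVConfig = CVConfig(),
    pipeline: PipelineParams = PipelineParams(),
    sim_l: SimilarityMatrix | None = None,
    sim_d: SimilarityMatrix | None = None,
) -> pd.DataFrame:
    """Repeated-CV mean AUC for every (K, P) combination of WKNKN settings."""
    if not len(list(K_values)) or not len(list(P_values)):
        raise ValueError("K and P value lists must be nonempty")
    rows = []
    for K in K_values:
        for P in P_values:
            pp = replace(pipeline, wknkn_params=WknknParams(K=int(K), P=float(P)))
            res = cv_pairs(Y, cfg, pp, sim_l, sim_d)
            rows.append(
                {"K": int(K), "P": float(P),
                 "mean_auc": res.mean_auc, "std_auc": res.std_auc}
            )
    return pd.DataFrame(rows)
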