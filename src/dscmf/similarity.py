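"""Similarity construction: expression, DAG-semantic, GIP kernels, fusion.

Four similarity sources feed the factorization. lncRNA expression similarity
is Spearman rank correlation between tissue profiles, mapped to [0, 1].
Disease semantic similarity scores shared ancestry in an ontology DAG, with
ancestor contributions decaying by a factor delta per generation. Gaussian
interaction profile (GIP) kernels measure how alike two entities' rows (or
columns) of the association matrix are. Expression/semantic similarity and
the GIP kernel are fused by a convex combination with weight alpha.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist
from scipy.stats import rankdata

from .datatypes import (
    AssociationMatrix,
    DiseaseDAG,
    ExpressionMatrix,
    SimilarityMatrix,
    warn_data,
)

__all__ = [
    "SemanticParams",
    "GipParams",
    "FusionParams",
    "expression_similarity",
    "semantic_value",
    "semantic_similarity",
    "gip_kernel",
    "fuse",
]


@dataclass(frozen=True)
class SemanticParams:
    """Semantic contribution factor delta in (0, 1]; each generation of
    ancestry multiplies a disease's contribution by delta."""

    delta: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.delta <= 1:
            raise ValueError("delta must lie in (0, 1]")


@dataclass(frozen=True)
class GipParams:
    """Pre-normalization bandwidth scale gamma'.

    The effective bandwidth is gamma = gamma' / mean_i ||profile_i||^2, the
    interaction-profile convention that makes the kernel invariant to the
    overall density of the association matrix.
    """

    gamma_prime: float = 1.0

    def __post_init__(self) -> None:
        if self.gamma_prime <= 0:
            raise ValueError("gamma_prime must be positive")


@dataclass(frozen=True)
class FusionParams:
    """Convex-combination weight alpha in [0, 1] on the non-GIP similarity."""

    alpha: float = 0.5

    def __post_init__(self) -> None:
        if not 0 <= self.alpha <= 1:
            raise ValueError("alpha must lie in [0, 1]")


def expression_similarity(
    expr: ExpressionMatrix, raw: bool = False
) -> SimilarityMatrix:
    """Pairwise Spearman correlation of expression rows.

    By default rho is mapped to ``(rho + 1) / 2`` so the result is a
    nonnegative unit-diagonal similarity; ``raw=True`` keeps rho itself.
    Rows with constant expression have undefined rank correlation; their
    off-diagonal similarity is set to the neutral value (0.5 mapped, 0 raw).
    """
    values = expr.values
    if values.shape[1] < 2:
        raise ValueError("expression similarity needs at least 2 samples")
    n = values.shape[0]
    constant = values.std(axis=1) == 0
    if constant.any():
        names = [expr.lncrna_ids[i] for i in np.nonzero(constant)[0]]
        warn_data(f"constant expression rows {names}: similarity set to neutral")

    ranks = np.apply_along_axis(rankdata, 1, values)
    ranks = ranks - ranks.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(ranks, axis=1)
    safe = np.where(norms == 0, 1.0, norms)
    rho = (ranks / safe[:, None]) @ (ranks / safe[:, None]).T
    rho = np.clip(rho, -1.0, 1.0)
    rho[constant, :] = 0.0
    rho[:, constant] = 0.0

    sim = rho if raw else (rho + 1.0) / 2.0
    np.fill_diagonal(sim, 1.0)
    sim = (sim + sim.T) / 2.0
    return SimilarityMatrix(expr.lncrna_ids, sim,
                            role="generic" if raw else "expression")


def _ancestor_closure(dag: DiseaseDAG, disease: str) -> set[str]:
    return {disease} | dag.ancestors(disease)


def semantic_value(
    dag: DiseaseDAG, disease: str, params: SemanticParams = SemanticParams()
) -> tuple[dict[str, float], float]:
    """Per-ancestor semantic contributions and their sum DV.

    The disease itself contributes 1. Every ancestor ``t`` contributes the
    maximum over its children inside the ancestor closure of delta times the
    child's contribution, so contributions decay geometrically with distance
    along the most direct path.
    """
    closure = _ancestor_closure(dag, disease)
    contrib: dict[str, float] = {}

    def value_of(t: str) -> float:
        if t in contrib:
            return contrib[t]
        if t == disease:
            contrib[t] = 1.0
            return 1.0
        kids = [c for c in dag.children(t) if c in closure]
        v = max(params.delta * value_of(c) for c in kids)
        contrib[t] = v
        return v

    for t in closure:
        value_of(t)
    return contrib, float(sum(contrib.values()))


def semantic_similarity(
    dag: DiseaseDAG,
    diseases: list[str],
    params: SemanticParams = SemanticParams(),
) -> SimilarityMatrix:
    """DAG semantic similarity over a disease list.

    ``S(d_i, d_j)`` sums, over shared ancestors ``t``, the contributions of
    ``t`` to both diseases, normalized by ``DV(d_i) + DV(d_j)``. Diseases
    with disjoint ancestor closures score 0; the diagonal is exactly 1.
    """
    contribs = []
    dvs = []
    for d in diseases:
        c, dv = semantic_value(dag, d, params)
        contribs.append(c)
        dvs.append(dv)
    n = len(diseases)
    S = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            shared = contribs[i].keys() & contribs[j].keys()
            if shared:
                num = sum(contribs[i][t] + contribs[j][t] for t in shared)
                S[i, j] = S[j, i] = num / (dvs[i] + dvs[j])
    return SimilarityMatrix(list(diseases), S, role="semantic")


def gip_kernel(
    Y: AssociationMatrix,
    axis: str = "lncrna",
    params: GipParams = GipParams(),
) -> SimilarityMatrix:
    """Gaussian interaction profile kernel over rows or columns of Y.

    ``K(i, j) = exp(-gamma ||Y(i) - Y(j)||^2)`` with
    ``gamma = gamma' / mean_i ||Y(i)||^2``. The kernel is symmetric,
    unit-diagonal and positive semidefinite.
    """
    if axis == "lncrna":
        profiles, ids = Y.values, Y.lncrna_ids
    elif axis == "disease":
        profiles, ids = Y.values.T, Y.disease_ids
    else:
        raise ValueError("axis must be 'lncrna' or 'disease'")
    mean_sq = float(np.mean(np.sum(profiles**2, axis=1)))
    if mean_sq == 0:
        raise ValueError("bandwidth undefined: association matrix is all zero")
    gamma = params.gamma_prime / mean_sq
    sq_dists = squareform(pdist(profiles, metric="sqeuclidean")) if len(ids) > 1 \
        else np.zeros((1, 1))
    K = np.exp(-gamma * sq_dists)
    np.fill_diagonal(K, 1.0)
    K = (K + K.T) / 2.0
    return SimilarityMatrix(list(ids), K, role="gip")


def fuse(
    sim: SimilarityMatrix,
    gip: SimilarityMatrix,
    params: FusionParams = FusionParams(),
) -> SimilarityMatrix:
    """Convex combination ``K = alpha * sim + (1 - alpha) * gip``."""
    if sim.ids != gip.ids:
        raise ValueError("fuse requires matching ids in matching order")
    K = params.alpha * sim.values + (1.0 - params.alpha) * gip.values
    return SimilarityMatrix(list(sim.ids), K, role="fused")
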