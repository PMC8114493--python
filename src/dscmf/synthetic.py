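"""Synthetic generators for every input class, plus the 2-D robustness study.

Everything the pipeline consumes can be generated here so the whole package
is testable without external downloads: a planted low-rank binary association
matrix (standing in for a curated lncRNA-disease gold standard), a layered
random ontology DAG, block-correlated expression profiles, and the classic
subspace-recovery robustness setup -- points on the line y = x contaminated
with off-line noise, factored at rank 1 by both the CMF baseline and the
L2,1-regularized DSCMF variant.

All generators are pure functions of their seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import AssociationMatrix, DiseaseDAG, ExpressionMatrix
from .factorization import DscmfConfig, fit

__all__ = [
    "PlantedModel",
    "LineDataset",
    "generate_association",
    "generate_dag",
    "generate_expression",
    "line_with_noise",
    "robustness_experiment",
]


@dataclass(frozen=True)
class PlantedModel:
    """Low-rank planted association model.

    Latent factors are standard normal; the binary matrix marks the top
    ``density`` quantile of the latent scores, then ``noise_flip_rate`` of
    the entries are flipped.
    """

    n_l: int = 40
    n_d: int = 30
    true_rank: int = 3
    density: float = 0.08
    noise_flip_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.density < 1:
            raise ValueError("density must lie in (0, 1)")
        if not 0 <= self.noise_flip_rate < 0.5:
            raise ValueError("noise_flip_rate must lie in [0, 0.5)")
        if self.true_rank < 1 or self.true_rank > min(self.n_l, self.n_d):
            raise ValueError("true_rank must lie in [1, min(n_l, n_d)]")


@dataclass(frozen=True)
class LineDataset:
    """2-D point cloud: inliers exactly on y = x plus off-line noise."""

    points: np.ndarray
    n_inliers: int
    n_noise: int
    seed: int


def generate_association(model: PlantedModel) -> tuple[AssociationMatrix, np.ndarray]:
    """Planted binary association matrix and its latent truth scores."""
    rng = np.random.default_rng(model.seed)
    A = rng.standard_normal((model.n_l, model.true_rank))
    B = rng.standard_normal((model.n_d, model.true_rank))
    truth = A @ B.T
    n_ones = round(model.density * truth.size)
    threshold = np.sort(truth, axis=None)[-n_ones]
    Y = (truth >= threshold).astype(float)
    n_flips = round(model.noise_flip_rate * Y.size)
    if n_flips:
        flat = rng.choice(Y.size, size=n_flips, replace=False)
        Y.flat[flat] = 1.0 - Y.flat[flat]
    if Y.sum() == 0 or Y.sum() == Y.size:
        raise ValueError("degenerate density: planted matrix is constant")
    lnc_ids = [f"l{i:03d}" for i in range(model.n_l)]
    dis_ids = [f"d{j:03d}" for j in range(model.n_d)]
    return AssociationMatrix(lnc_ids, dis_ids, Y), truth


def generate_dag(n_nodes: int, n_layers: int, seed: int = 0) -> DiseaseDAG:
    """Layered random DAG: each non-root node gets 1-2 parents from the
    layer above, so the graph is acyclic by construction."""
    if n_layers < 1 or n_nodes < 1:
        raise ValueError("need n_layers >= 1 and n_nodes >= 1")
    rng = np.random.default_rng(seed)
    names = [f"D{i:03d}" for i in range(n_nodes)]
    layers: list[list[str]] = [[] for _ in range(min(n_layers, n_nodes))]
    for i, name in enumerate(names):
        layers[i % len(layers)].append(name)
    edges: set[tuple[str, str]] = set()
    for depth in range(1, len(layers)):
        above = layers[depth - 1]
        for child in layers[depth]:
            n_parents = int(rng.integers(1, min(2, len(above)) + 1))
            parents = rng.choice(len(above), size=n_parents, replace=False)
            for p in parents:
                edges.add((child, above[int(p)]))
    return DiseaseDAG(set(names), edges)


def generate_expression(
    lncrna_ids: list[str],
    n_samples: int = 16,
    block_sizes: list[int] | None = None,
    seed: int = 0,
    within_block_noise: float = 0.5,
) -> ExpressionMatrix:
    """Block-correlated Gaussian expression profiles.

    Members of a block share a latent profile plus independent noise, so
    expression similarity recovers the blocks (within-block similarity
    exceeds between-block on average).
    """
    if n_samples < 3:
        raise ValueError("need at least 3 samples")
    n = len(lncrna_ids)
    if block_sizes is None:
        block_sizes = [n]
    if sum(block_sizes) != n:
        raise ValueError("block sizes must sum to the number of lncRNAs")
    rng = np.random.default_rng(seed)
    values = np.empty((n, n_samples))
    row = 0
    for size in block_sizes:
        latent = rng.standard_normal(n_samples)
        for _ in range(size):
            values[row] = latent + within_block_noise * rng.standard_normal(n_samples)
            row += 1
    return ExpressionMatrix(list(lncrna_ids), [f"s{j:02d}" for j in range(n_samples)],
                            values)


def line_with_noise(
    n_inliers: int = 200,
    n_noise: int = 0,
    seed: int = 0,
    coord_range: tuple[float, float] = (-10.0, 10.0),
    band_frac: float = 0.1,
) -> LineDataset:
    """Points on y = x plus uniform off-line noise.

    Inliers are uniform along the line over ``coord_range``. Noise points are
    uniform over the bounding square, rejection-sampled to stay outside a
    band of width ``band_frac`` times the square side around the line, so
    noise is genuinely off-subspace.
    """
    if n_noise < 0:
        raise ValueError("n_noise must be >= 0")
    rng = np.random.default_rng(seed)
    lo, hi = coord_range
    x = rng.uniform(lo, hi, size=n_inliers)
    inliers = np.column_stack([x, x])
    noise_pts = []
    band = band_frac * (hi - lo)
    while len(noise_pts) < n_noise:
        p = rng.uniform(lo, hi, size=2)
        if abs(p[1] - p[0]) >= band:
            noise_pts.append(p)
    pts = np.vstack([inliers] + ([np.array(noise_pts)] if noise_pts else []))
    return LineDataset(pts, n_inliers, n_noise, seed)


_TRUE_DIRECTION = np.array([1.0, 1.0]) / np.sqrt(2.0)


def _direction_error(b: np.ndarray) -> float:
    b = b / np.linalg.norm(b)
    return float(np.arccos(min(1.0, abs(float(b @ _TRUE_DIRECTION)))))


def robustness_experiment(
    data: LineDataset,
    lambda_h: float = 4.0,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> tuple[float, float]:
    """Rank-1 direction recovery under noise: CMF vs DSCMF.

    The point cloud is the n x 2 matrix to factor at rank 1 with no side
    kernels. The recovered direction is the (normalized) single column of B;
    the returned pair is the angular error of (CMF, DSCMF) against the true
    subspace direction (1, 1)/sqrt(2). DSCMF uses the exact row-wise L2,1
    solve: at rank 1 the row reweights act as per-point soft-thresholding of
    the coefficients, so off-subspace points with weak projections drop out
    of the direction update -- the mechanism behind the method's robustness.
    """
    M = data.points
    # inlier range is symmetric about the origin, so no centering is needed
    common = dict(k=1, lambda_l=0.0, lambda_d=0.0, max_iter=max_iter, tol=tol)
    cmf_cfg = DscmfConfig(lambda_h=lambda_h, **common)
    dscmf_cfg = DscmfConfig(lambda_h=lambda_h, l21_exact=True, **common)
    res_cmf = fit(M, None, None, cmf_cfg, variant="cmf")
    res_dscmf = fit(M, None, None, dscmf_cfg, variant="dscmf")
    return (
        _direction_error(res_cmf.factors.B[:, 0]),
        _direction_error(res_dscmf.factors.B[:, 0]),
    )
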