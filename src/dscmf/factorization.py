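"""Dual sparse collaborative matrix factorization (DSCMF) and its CMF baseline.

The model factorizes an association matrix Y (n_l x n_d, possibly
WKNKN-imputed) as A B^T with A (n_l x k) and B (n_d x k), minimizing

    ||Y - A B^T||_F^2
    + lambda_h (||A||_F^2 + ||B||_F^2)            Tikhonov
    + lambda_h (||A||_{2,1} + ||B||_{2,1})        row sparsity (DSCMF only)
    + lambda_l ||K_l - A A^T||_F^2                lncRNA co-regularization
    + lambda_d ||K_d - B B^T||_F^2                disease co-regularization

where ||A||_{2,1} is the sum of Euclidean row norms and K_l, K_d are fused
similarity kernels. The L2,1 terms are handled by iterative reweighting:
diagonal matrices D1, D2 with entries 1/(2 ||row_j||_2) are recomputed each
outer iteration, and A, B are refreshed by alternating regularized
least-squares-style updates

    A <- (Y B + lambda_l K_l A) (B^T B + lambda_h I_k
          + lambda_l A^T A + lambda_h * d1 * I_k)^{-1}

(mirrored for B). Stated this way, the reweighting term couples an n_l x n_l
diagonal into a k x k Gram matrix, which is dimensionally inconsistent; two
consistent readings are provided. The default (``l21_exact=True``) solves one
k x k system per row with that row's own reweight. This is the exact
stationary condition of the iteratively reweighted objective, it is the
reading under which the L2,1 term can downweight individual rows (the source
of the method's robustness), and it inherits the IRLS majorize-minimize
descent guarantee. ``l21_exact=False`` instead replaces D1 by the scalar
mean of its diagonal -- a single k x k solve that coincides with the exact
solve when all row norms are equal, but averages away the per-row shrinkage
and with it the descent guarantee; it is kept as a cheap approximation. The
per-row systems share their Gram matrix up to a scalar diagonal shift, so
the exact mode costs one eigendecomposition plus O(k^2) per row. Linear
systems are solved by dense factorization, never by explicit inverse.

Factors are initialized from the top-k truncated SVD of Y:
A = U_k S_k^{1/2}, B = V_k S_k^{1/2}.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.linalg

from .datatypes import AssociationMatrix, SimilarityMatrix

__all__ = [
    "DscmfConfig",
    "FactorPair",
    "FitResult",
    "objective",
    "svd_init",
    "row_reweights",
    "update_A",
    "update_B",
    "fit",
    "predict",
    "rank_candidates",
]

VARIANTS = ("dscmf", "cmf")


@dataclass(frozen=True)
class DscmfConfig:
    """Hyperparameters of the factorization.

    ``k=None`` resolves to ``min(n_l, n_d) // 2`` at fit time. ``epsilon``
    guards the reweights 1/(2 max(||row||, epsilon)) against zero rows.
    """

    k: int | None = None
    lambda_h: float = 1.0
    lambda_l: float = 0.01
    lambda_d: float = 0.01
    max_iter: int = 100
    tol: float = 1e-6
    epsilon: float = 1e-8
    seed: int = 0
    l21_exact: bool = True

    def __post_init__(self) -> None:
        if self.k is not None and self.k < 1:
            raise ValueError("rank k must be >= 1")
        if self.lambda_h < 0:
            raise ValueError("lambda_h must be >= 0")
        if self.lambda_l < 0 or self.lambda_d < 0:
            raise ValueError("lambda_l and lambda_d must be >= 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.tol <= 0 or self.epsilon <= 0:
            raise ValueError("tol and epsilon must be > 0")

    def resolve_k(self, n_l: int, n_d: int) -> int:
        k = self.k if self.k is not None else max(1, min(n_l, n_d) // 2)
        if k > min(n_l, n_d):
            raise ValueError(f"rank k={k} exceeds min dimension {min(n_l, n_d)}")
        return k


@dataclass
class FactorPair:
    """Latent factors A (n_l x k), B (n_d x k) and reweight diagonals D1, D2."""

    A: np.ndarray
    B: np.ndarray
    D1: np.ndarray = field(default=None)  # type: ignore[assignment]
    D2: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        if self.A.ndim != 2 or self.B.ndim != 2 or self.A.shape[1] != self.B.shape[1]:
            raise ValueError("A and B must be 2-D with a common latent rank")
        if not (np.all(np.isfinite(self.A)) and np.all(np.isfinite(self.B))):
            raise ValueError("factor matrices contain non-finite entries")
        if self.D1 is None:
            self.D1 = row_reweights(self.A)
        if self.D2 is None:
            self.D2 = row_reweights(self.B)

    @property
    def k(self) -> int:
        return self.A.shape[1]

    def refresh_reweights(self, epsilon: float = 1e-8) -> None:
        self.D1 = row_reweights(self.A, epsilon)
        self.D2 = row_reweights(self.B, epsilon)


@dataclass
class FitResult:
    factors: FactorPair
    objective_trace: list[float]
    iterations_run: int
    converged: bool


def row_reweights(M: np.ndarray, epsilon: float = 1e-8) -> np.ndarray:
    """IRLS diagonal for the L2,1 norm: d_jj = 1 / (2 max(||M_j||_2, eps))."""
    norms = np.linalg.norm(M, axis=1)
    return 1.0 / (2.0 * np.maximum(norms, epsilon))


def _kernel_values(K: SimilarityMatrix | np.ndarray | None) -> np.ndarray | None:
    if K is None:
        return None
    return K.values if isinstance(K, SimilarityMatrix) else np.asarray(K, float)


def _y_values(Y: AssociationMatrix | np.ndarray) -> np.ndarray:
    return Y.values if isinstance(Y, AssociationMatrix) else np.asarray(Y, float)


def objective(
    Y: AssociationMatrix | np.ndarray,
    Kl: SimilarityMatrix | np.ndarray | None,
    Kd: SimilarityMatrix | np.ndarray | None,
    factors: FactorPair,
    cfg: DscmfConfig,
    variant: str = "dscmf",
) -> float:
    """Evaluate the (DSCMF or CMF) objective at the given factors.

    ``Kl``/``Kd`` may be None when the corresponding lambda is zero.
    """
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}")
    Yv = _y_values(Y)
    A, B = factors.A, factors.B
    if not (np.all(np.isfinite(A)) and np.all(np.isfinite(B))):
        raise ValueError("factor matrices contain non-finite entries")
    val = float(np.linalg.norm(Yv - A @ B.T, "fro") ** 2)
    val += cfg.lambda_h * float(
        np.linalg.norm(A, "fro") ** 2 + np.linalg.norm(B, "fro") ** 2
    )
    if variant == "dscmf":
        val += cfg.lambda_h * float(
            np.linalg.norm(A, axis=1).sum() + np.linalg.norm(B, axis=1).sum()
        )
    if cfg.lambda_l:
        Klv = _kernel_values(Kl)
        if Klv is None:
            raise ValueError("lambda_l > 0 requires a lncRNA kernel")
        val += cfg.lambda_l * float(np.linalg.norm(Klv - A @ A.T, "fro") ** 2)
    if cfg.lambda_d:
        Kdv = _kernel_values(Kd)
        if Kdv is None:
            raise ValueError("lambda_d > 0 requires a disease kernel")
        val += cfg.lambda_d * float(np.linalg.norm(Kdv - B @ B.T, "fro") ** 2)
    return val


def svd_init(Y: AssociationMatrix | np.ndarray, k: int) -> FactorPair:
    """A = U_k S_k^{1/2}, B = V_k S_k^{1/2} from the top-k SVD of Y."""
    Yv = _y_values(Y)
    if k > min(Yv.shape):
        raise ValueError(f"rank k={k} exceeds min dimension {min(Yv.shape)}")
    U, s, Vt = np.linalg.svd(Yv, full_matrices=False)
    root = np.sqrt(s[:k])
    A = U[:, :k] * root
    B = Vt[:k].T * root
    return FactorPair(A, B)


def _solve_right(M: np.ndarray, G: np.ndarray) -> np.ndarray:
    """Solve X G = M for X with G symmetric, via factorization."""
    return scipy.linalg.solve(G, M.T, assume_a="sym").T


def _update_factor(
    target: np.ndarray,
    kernel: np.ndarray | None,
    F_old: np.ndarray,
    other: np.ndarray,
    lam_side: float,
    reweights: np.ndarray,
    cfg: DscmfConfig,
    variant: str,
) -> np.ndarray:
    """Shared machinery: update A with (Y, Kl, A, B, lambda_l, D1) or
    B with (Y^T, Kd, B, A, lambda_d, D2)."""
    k = F_old.shape[1]
    rhs = target @ other
    if lam_side:
        if kernel is None:
            raise ValueError("side regularization requires its kernel")
        rhs = rhs + lam_side * kernel @ F_old
    base = other.T @ other + cfg.lambda_h * np.eye(k)
    if lam_side:
        base = base + lam_side * F_old.T @ F_old
    try:
        if variant == "cmf":
            return _solve_right(rhs, base)
        if cfg.l21_exact:
            # the per-row systems share `base` and differ only by a scalar on
            # the diagonal: one eigendecomposition solves all rows at O(k^2)
            w, Q = scipy.linalg.eigh(base)
            proj = rhs @ Q
            denom = w[None, :] + cfg.lambda_h * reweights[:, None]
            if denom.min() <= 0:
                raise np.linalg.LinAlgError(
                    "singular update system; consider increasing lambda_h"
                )
            return (proj / denom) @ Q.T
        d_bar = float(np.mean(reweights))
        return _solve_right(rhs, base + cfg.lambda_h * d_bar * np.eye(k))
    except scipy.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            f"singular update system ({err}); consider increasing lambda_h"
        ) from None


def update_A(
    Y: AssociationMatrix | np.ndarray,
    Kl: SimilarityMatrix | np.ndarray | None,
    factors: FactorPair,
    cfg: DscmfConfig,
    variant: str = "dscmf",
) -> np.ndarray:
    """One reweighted least-squares refresh of the lncRNA factor A."""
    return _update_factor(
        _y_values(Y), _kernel_values(Kl), factors.A, factors.B,
        cfg.lambda_l, factors.D1, cfg, variant,
    )


def update_B(
    Y: AssociationMatrix | np.ndarray,
    Kd: SimilarityMatrix | np.ndarray | None,
    factors: FactorPair,
    cfg: DscmfConfig,
    variant: str = "dscmf",
) -> np.ndarray:
    """One reweighted least-squares refresh of the disease factor B."""
    return _update_factor(
        _y_values(Y).T, _kernel_values(Kd), factors.B, factors.A,
        cfg.lambda_d, factors.D2, cfg, variant,
    )


def fit(
    Y: AssociationMatrix | np.ndarray,
    Kl: SimilarityMatrix | np.ndarray | None,
    Kd: SimilarityMatrix | np.ndarray | None,
    cfg: DscmfConfig = DscmfConfig(),
    variant: str = "dscmf",
) -> FitResult:
    """Alternate A/B updates from an SVD start until the relative objective
    change falls below ``cfg.tol`` or ``cfg.max_iter`` iterations elapse.

    The reweight diagonals D1, D2 are refreshed from the current factors at
    the top of every iteration (standard IRLS schedule). The objective is
    recorded after each full (A, B) sweep; the trace includes the initial
    value, so its length is ``iterations_run + 1``.
    """
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}")
    Yv = _y_values(Y)
    k = cfg.resolve_k(*Yv.shape)
    factors = svd_init(Yv, k)
    trace = [objective(Yv, Kl, Kd, factors, cfg, variant)]
    converged = False
    iterations = 0
    for it in range(1, cfg.max_iter + 1):
        factors.refresh_reweights(cfg.epsilon)
        factors.A = update_A(Yv, Kl, factors, cfg, variant)
        factors.B = update_B(Yv, Kd, factors, cfg, variant)
        obj = objective(Yv, Kl, Kd, factors, cfg, variant)
        if not np.isfinite(obj):
            raise FloatingPointError(f"objective became non-finite at iteration {it}")
        trace.append(obj)
        iterations = it
        denom = max(abs(trace[-2]), 1e-300)
        if abs(trace[-1] - trace[-2]) / denom < cfg.tol:
            converged = True
            break
    factors.refresh_reweights(cfg.epsilon)
    return FitResult(factors, trace, iterations, converged)


def predict(factors: FactorPair) -> np.ndarray:
    """Predicted association scores A B^T."""
    return factors.A @ factors.B.T


def rank_candidates(
    scores: np.ndarray,
    Y: AssociationMatrix,
    disease: str,
    include_known: bool = True,
) -> list[tuple[str, float]]:
    """Candidate lncRNAs for one disease, sorted by descending score.

    Ties break by ascending lncRNA id. ``include_known=False`` drops pairs
    already marked 1 in ``Y`` (known positives are kept by default, matching
    how ranked prediction tables are usually presented).
    """
    j = Y.disease_index(disease)
    scores = np.asarray(scores, dtype=float)
    if scores.shape != Y.shape:
        raise ValueError("scores shape must match the association matrix")
    entries = [
        (lnc, float(scores[i, j]))
        for i, lnc in enumerate(Y.lncrna_ids)
        if include_known or Y.values[i, j] == 0
    ]
    entries.sort(key=lambda e: (-e[1], e[0]))
    return entries
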