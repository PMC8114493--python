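"""WKNKN: weighted K-nearest-known-neighbor imputation of unknown zeros.

A curated association matrix records verified links as 1 and everything else
as 0, but most 0s are merely unobserved. WKNKN replaces them with a weighted
average of the profiles of the K most similar neighbors that have at least
one known association, with geometrically decaying weights P^(t-1) on the
t-th nearest neighbor, normalized by the sum of neighbor similarities. Row
(lncRNA-side) and column (disease-side) estimates are averaged and combined
with the original matrix by an elementwise maximum, so known positives are
always preserved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import AssociationMatrix, SimilarityMatrix, warn_data

__all__ = ["WknknParams", "wknkn"]


@dataclass(frozen=True)
class WknknParams:
    """Neighbor count K >= 1 and decay factor P in (0, 1]."""

    K: int = 5
    P: float = 0.7

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if not 0 < self.P <= 1:
            raise ValueError("P must lie in (0, 1]")


def _neighbor_estimate(
    Y: np.ndarray,
    sim: np.ndarray,
    ids: list[str],
    params: WknknParams,
) -> np.ndarray:
    """Row-side weighted neighbor profiles; call with Y.T for the column side."""
    n = Y.shape[0]
    known = Y.sum(axis=1) > 0
    est = np.zeros_like(Y)
    short = False
    for i in range(n):
        candidates = [j for j in range(n) if j != i and known[j]]
        # nearest first; equal similarities broken by ascending id
        candidates.sort(key=lambda j: (-sim[i, j], ids[j]))
        if len(candidates) < params.K:
            short = True
        neighbors = candidates[: params.K]
        z = sum(sim[i, j] for j in neighbors)
        if z == 0 or not neighbors:
            continue
        acc = np.zeros(Y.shape[1])
        for t, j in enumerate(neighbors):
            acc += params.P**t * sim[i, j] * Y[j]
        est[i] = acc / z
    if short:
        warn_data(
            f"fewer than K={params.K} neighbors with known associations; "
            "used all available"
        )
    return est


def wknkn(
    Y: AssociationMatrix,
    sim_l: SimilarityMatrix,
    sim_d: SimilarityMatrix,
    params: WknknParams = WknknParams(),
) -> AssociationMatrix:
    """Impute unknown zeros of ``Y`` from both axes' nearest known neighbors.

    Returns a matrix with entries in [0, 1] that dominates ``Y`` elementwise.
    """
    if sim_l.ids != Y.lncrna_ids:
        raise ValueError("sim_l ids must match Y lncRNA ids in order")
    if sim_d.ids != Y.disease_ids:
        raise ValueError("sim_d ids must match Y disease ids in order")
    Yv = Y.values
    est_l = _neighbor_estimate(Yv, sim_l.values, Y.lncrna_ids, params)
    est_d = _neighbor_estimate(Yv.T, sim_d.values, Y.disease_ids, params).T
    imputed = np.maximum(Yv, (est_l + est_d) / 2.0)
    return AssociationMatrix(
        list(Y.lncrna_ids), list(Y.disease_ids), np.clip(imputed, 0.0, 1.0)
    )
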