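"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written naively (explicit loops, no shared code with the
package) so agreement with the package is a meaningful check.
"""

from __future__ import annotations

import math

import numpy as np


def objective_bruteforce(Y, Kl, Kd, A, B, lambda_h, lambda_l, lambda_d,
                         variant="dscmf"):
    """Term-by-term evaluation of the factorization objective."""
    n_l, n_d = Y.shape
    k = A.shape[1]
    resid = 0.0
    for i in range(n_l):
        for j in range(n_d):
            pred = sum(A[i, t] * B[j, t] for t in range(k))
            resid += (Y[i, j] - pred) ** 2
    fro_a = sum(A[i, t] ** 2 for i in range(n_l) for t in range(k))
    fro_b = sum(B[j, t] ** 2 for j in range(n_d) for t in range(k))
    total = resid + lambda_h * (fro_a + fro_b)
    if variant == "dscmf":
        l21_a = sum(math.sqrt(sum(A[i, t] ** 2 for t in range(k)))
                    for i in range(n_l))
        l21_b = sum(math.sqrt(sum(B[j, t] ** 2 for t in range(k)))
                    for j in range(n_d))
        total += lambda_h * (l21_a + l21_b)
    if lambda_l:
        for i in range(n_l):
            for j in range(n_l):
                pred = sum(A[i, t] * A[j, t] for t in range(k))
                total += lambda_l * (Kl[i, j] - pred) ** 2
    if lambda_d:
        for i in range(n_d):
            for j in range(n_d):
                pred = sum(B[i, t] * B[j, t] for t in range(k))
                total += lambda_d * (Kd[i, j] - pred) ** 2
    return total


def update_A_oracle(Y, Kl, A_old, B, lambda_h, lambda_l, reweights,
                    mode="exact"):
    """Independently assembled stationarity system for the A refresh.

    ``mode='exact'``: each row j solves
        a_j (B^T B + lh I + ll A^T A + lh d_j I) = (Y B + ll Kl A)_j
    ``mode='scalar'``: one system with mean(d) in place of d_j.
    """
    k = A_old.shape[1]
    rhs = Y @ B
    if lambda_l:
        rhs = rhs + lambda_l * (Kl @ A_old)
    base = B.T @ B + lambda_h * np.eye(k)
    if lambda_l:
        base = base + lambda_l * (A_old.T @ A_old)
    if mode == "scalar":
        G = base + lambda_h * float(np.mean(reweights)) * np.eye(k)
        return rhs @ np.linalg.inv(G)
    out = np.empty_like(A_old)
    for j in range(A_old.shape[0]):
        G = base + lambda_h * reweights[j] * np.eye(k)
        out[j] = np.linalg.solve(G, rhs[j])
    return out


def semantic_value_oracle(parent_edges, disease, delta):
    """Memoization-free recursive evaluation of ancestor contributions."""
    parents = {}
    children = {}
    for c, p in parent_edges:
        parents.setdefault(c, set()).add(p)
        children.setdefault(p, set()).add(c)

    def closure(d):
        out = {d}
        stack = [d]
        while stack:
            for p in parents.get(stack.pop(), ()):
                if p not in out:
                    out.add(p)
                    stack.append(p)
        return out

    T = closure(disease)

    def contribution(t):
        if t == disease:
            return 1.0
        return max(delta * contribution(c)
                   for c in children.get(t, ()) if c in T)

    contrib = {t: contribution(t) for t in T}
    return contrib, sum(contrib.values())


def semantic_similarity_oracle(parent_edges, d1, d2, delta):
    c1, dv1 = semantic_value_oracle(parent_edges, d1, delta)
    c2, dv2 = semantic_value_oracle(parent_edges, d2, delta)
    shared = set(c1) & set(c2)
    if not shared:
        return 0.0
    return sum(c1[t] + c2[t] for t in shared) / (dv1 + dv2)


def wknkn_oracle(Y, sim_l, sim_d, ids_l, ids_d, K, P):
    """Naive nested-loop WKNKN."""
    n_l, n_d = Y.shape

    def side_estimate(M, sim, ids):
        n = M.shape[0]
        est = np.zeros_like(M)
        for i in range(n):
            cands = [j for j in range(n) if j != i and M[j].sum() > 0]
            cands.sort(key=lambda j: (-sim[i, j], ids[j]))
            neigh = cands[:K]
            z = sum(sim[i, j] for j in neigh)
            if not neigh or z == 0:
                continue
            for col in range(M.shape[1]):
                s = 0.0
                for t, j in enumerate(neigh):
                    s += (P ** t) * sim[i, j] * M[j, col]
                est[i, col] = s / z
        return est

    est_l = side_estimate(Y, sim_l, ids_l)
    est_d = side_estimate(Y.T, sim_d, ids_d).T
    out = np.empty_like(Y)
    for i in range(n_l):
        for j in range(n_d):
            out[i, j] = max(Y[i, j], (est_l[i, j] + est_d[i, j]) / 2.0)
    return out


def auc_pairwise(scores, labels):
    """AUC as the tie-aware fraction of concordant positive/negative pairs."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))
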