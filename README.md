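# dscmf

Dual sparse collaborative matrix factorization for predicting lncRNA–disease
associations (and bipartite link prediction in general).

## The problem

Experimentally verified lncRNA–disease associations (LDAs) are sparse: a
curated matrix **Y** ∈ {0,1}^(n_l × n_d) marks verified pairs with 1, but
most 0s are unstudied rather than refuted. The task is to rank the unknown
pairs so that true-but-unverified associations surface at the top. This
package is for computational biologists who want a tested, reproducible
implementation of a similarity-regularized matrix-factorization pipeline for
this task — with synthetic generators so every stage can be exercised and
validated without any external download.

## The model

DSCMF factorizes **Y** ≈ **AB**ᵀ with **A** ∈ ℝ^(n_l × k),
**B** ∈ ℝ^(n_d × k), minimizing

```
‖Y − ABᵀ‖²_F + λ_h(‖A‖²_F + ‖B‖²_F) + λ_h(‖A‖₂,₁ + ‖B‖₂,₁)
            + λ_l‖K_l − AAᵀ‖²_F + λ_d‖K_d − BBᵀ‖²_F
```

where ‖·‖₂,₁ is the sum of Euclidean row norms (row sparsity), and **K_l**,
**K_d** are fused similarity kernels: a convex combination (weight α) of
profile-derived similarity — Spearman correlation of tissue expression for
lncRNAs, DAG-ancestry semantic similarity for diseases — with Gaussian
interaction profile (GIP) kernels computed from **Y** itself. Dropping the
two L2,1 terms gives the classical collaborative matrix factorization (CMF)
baseline.

Before fitting, WKNKN preprocessing replaces unknown zeros with decayed,
similarity-weighted averages of each entity's K nearest neighbors that have
known associations (defaults K=5, P=0.7).

Optimization: factors are initialized from the truncated SVD of **Y**
(A = U_k S_k^½, B = V_k S_k^½) and refined by alternating reweighted
least-squares updates; the L2,1 terms enter through iteratively reweighted
diagonal matrices D₁, D₂ with d_jj = 1/(2‖row_j‖₂), solved exactly per row.
Predicted scores are **AB**ᵀ; candidates for a disease are its score column
sorted descending.

## Worked example

`examples/04_cross_validation.py` evaluates the full pipeline on a planted
low-rank association matrix (40 lncRNAs × 30 diseases, rank 3, 8% density,
2% label noise) by repeated ten-fold pair cross-validation — known positives
are masked fold by fold, GIP kernels and WKNKN are recomputed inside every
fold, and masked pairs are scored against all unknown pairs:

```
$ python examples/04_cross_validation.py
dscmf: AUC 0.8148 (0.0346) over 3 repeats
cmf  : AUC 0.8127 (0.0389) over 3 repeats
```

AUC is the probability that a random held-out positive outscores a random
unknown pair (0.5 = chance); the parenthesized value is the standard
deviation over repeats. `examples/05_robustness.py` shows the effect of the
L2,1 penalty on rank-1 subspace recovery when off-line noise is added to 200
points on y = x:

```
$ python examples/05_robustness.py
noise  CMF error (rad)  DSCMF error (rad)
    0         0.000000           0.000000
    1         0.000879           0.000874
   30         0.001845           0.001599
   60         0.004883           0.004712
   90         0.007956           0.007612
```

The numbers are the angular error between the recovered direction and the
true subspace direction (1,1)/√2: both variants are exact without noise, and
the sparse variant degrades less as noise grows.

The other examples cover kernel construction (`01`), WKNKN imputation
(`02`), and fitting plus per-disease candidate ranking (`03`). A thin CLI
mirrors the stages (`dscmf similarity | preprocess | fit | predict | cv |
sensitivity | simulate | robustness`); every command writes a JSON manifest
of its resolved parameters and input hashes next to its outputs.

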