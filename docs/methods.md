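# Methods

## Model

The package predicts missing links in a binary bipartite association matrix
Y (rows: lncRNAs, columns: diseases) by collaborative matrix factorization
with dual row-sparsity. The fitted score matrix is A Bᵀ, where A (n_l × k)
and B (n_d × k) minimize

    f(A, B) = ‖Y − ABᵀ‖²_F
            + λ_h (‖A‖²_F + ‖B‖²_F)            (Tikhonov)
            + λ_h (‖A‖₂,₁ + ‖B‖₂,₁)            (row sparsity; DSCMF only)
            + λ_l ‖K_l − AAᵀ‖²_F               (lncRNA co-regularization)
            + λ_d ‖K_d − BBᵀ‖²_F               (disease co-regularization)

‖A‖₂,₁ = Σ_j ‖A_j‖₂ is the sum of row norms. The CMF baseline omits the two
L2,1 terms; everything else is shared. The co-regularization terms pull the
factor Gram matrices toward the similarity kernels, encoding the guilt-by-
association assumption: similar lncRNAs associate with similar diseases.

### Similarity kernels

* **lncRNA expression similarity** S_l: Spearman rank correlation between
  expression profiles, mapped to similarity by s = (ρ+1)/2 so the matrix is
  nonnegative with unit diagonal. The co-regularization term ‖K_l − AAᵀ‖²
  behaves poorly with negative "similarities", hence the affine map; the raw
  ρ matrix is available (`raw=True`) for users who prefer it. Rows with
  constant expression have undefined ρ; their off-diagonal similarity is the
  neutral 0.5 (0 raw) with a warning.
* **Disease semantic similarity** S_d: on a user-supplied ontology DAG, a
  disease contributes 1 to itself and each ancestor t contributes
  max{Δ · contribution(c)} over t's children c inside the disease's ancestor
  closure, with contribution factor Δ = 0.5 by default (the convention of
  the semantic-similarity literature this construction comes from). The
  similarity of two diseases sums the contributions of shared ancestors,
  normalized by the two total semantic values; diagonal exactly 1, disjoint
  ancestries score 0.
* **GIP kernels**: exp(−γ‖profile_i − profile_j‖²) over rows (lncRNAs) or
  columns (diseases) of Y, with γ = γ′ / mean_i‖profile_i‖² and γ′ = 1.
  Normalizing the bandwidth by the mean squared profile norm makes the
  kernel invariant to matrix density, the standard interaction-profile
  convention. An all-zero Y leaves the bandwidth undefined and is an error.
* **Fusion**: K = α S + (1−α) GIP elementwise, α = 0.5 by default. α is not
  dictated by anything structural; 0.5 weights measured side information and
  network topology equally and is configurable everywhere.

### WKNKN preprocessing

Unknown zeros are softened before fitting: for each lncRNA, the K most
similar lncRNAs with ≥ 1 known association (self excluded; similarity ties
broken by ascending identifier for determinism) contribute their association
profiles with geometric weights P^(t−1) on the t-th neighbor, normalized by
the sum of the K similarities; the disease side is computed symmetrically;
the two estimates are averaged and combined with Y by elementwise maximum.
Known 1s are therefore always preserved and the output stays in [0, 1].
Defaults K = 5, P = 0.7 (the setting at which AUC is stable in sensitivity
sweeps). WKNKN is not idempotent and is not claimed to be. With fewer than K
eligible neighbors, all available are used (logged); a zero similarity
normalizer yields a zero estimate for that row or column.

## Optimization

A and B are initialized from the top-k truncated SVD of Y
(A = U_k S_k^½, B = V_k S_k^½, so ABᵀ starts at the best rank-k
approximation) and refined by alternating updates. With the L2,1 terms
handled by iterative reweighting — diagonal matrices D₁, D₂ with
d_jj = 1/(2 max(‖row_j‖₂, ε)), ε = 1e-8, refreshed once per outer iteration
before the A update — the stationarity system for A given B is, per row j:

    A_j (BᵀB + λ_h I_k + λ_l AᵀA + λ_h d¹_jj I_k) = (YB + λ_l K_l A)_j

and symmetrically for B. Two solvers are provided:

* **Exact row-wise solve** (default). The per-row systems share their Gram
  matrix up to the scalar diagonal shift λ_h d_jj, so one eigendecomposition
  of the shared part solves all rows at O(k²) each. This is the exact
  stationary condition of the reweighted objective, and for the residual +
  Tikhonov + L2,1 part it is a majorize–minimize step: the quadratic
  surrogate Σ_j d_jj‖A_j‖² + Σ_j 1/(4 d_jj) touches ‖A‖₂,₁ at the current
  iterate, so the recorded objective cannot increase when λ_l = λ_d = 0.
  The per-row reweighting is also what gives the method its robustness: at
  rank 1 it reduces to per-point soft-thresholding of the coefficients (see
  the robustness experiment below).
* **Scalar-mean approximation** (`l21_exact=False`). Replaces D₁ by the mean
  of its diagonal, giving a single k × k solve. It coincides with the exact
  solve when all row norms are equal, but averaging the reweights removes
  the per-row shrinkage and with it the descent guarantee (no scalar weight
  can match the per-row gradients); it is kept as a cheap approximation and
  for comparison.

The co-regularization terms are quartic in the factors; the updates treat
AᵀA (resp. BᵀB) as fixed at the previous iterate, i.e. they are fixed-point
steps rather than exact minimizations for those terms. In practice the
objective trace is monotone at the default λ_l = λ_d = 0.01 up to relative
drift below 1e-4 per step, and strictly monotone (≤ 1e-9 relative) when the
side terms are off; the test suite pins both behaviors.

Linear systems are solved by dense symmetric factorization (or the shared
eigendecomposition); explicit matrix inversion is never formed. Iteration
stops when the relative objective change drops below `tol` (default 1e-6) or
after `max_iter` = 100 iterations; both the trace (including the initial
value) and the convergence flag are returned. A non-finite objective aborts
with the iteration index. Typical synthetic fits converge in 10–30
iterations.

Defaults: k = min(n_l, n_d) // 2 when unset (the matrices are far from full
rank and halving the minimum dimension leaves headroom without full
memorization; always configurable), λ_h = 1, λ_l = λ_d = 0.01. λ_h may be
set to 0, which disables both Tikhonov and L2,1 terms and reduces the update
to alternating least squares — useful as a limiting sanity check.

## Evaluation protocol

Pair cross-validation ("CV-p"): the known 1-entries are partitioned
uniformly at random into n_folds = 10 folds (every positive in exactly one
fold). Per fold, the held-out positives are zeroed in the training matrix
and the **whole** pipeline is re-run on it: GIP kernels are recomputed from
the fold's training matrix (they depend on Y, so reusing global kernels
would leak the held-out positives; `gip_global=True` restores the leaky
variant for comparison), fused with the fold-independent expression/semantic
similarities when provided, WKNKN is applied to the training matrix only,
and the factorization is fit. Fold AUC scores the masked positives against
all unknown (0) pairs of the original matrix — the standard protocol when no
verified negatives exist. The partition is repeated n_repeats times (30 by
default) and results are reported as mean and sample standard deviation
(ddof = 1) over repeats. AUC uses a full threshold sweep with ties counting
1/2, so it equals the normalized Mann–Whitney statistic.

Hyperparameter search evaluates an explicit grid of (λ_h, λ_l, λ_d) triples
— by default λ_h ∈ {2⁻², 2⁻¹, 2⁰, 2¹} crossed with side weights in
{0, 10⁻⁴, 10⁻³, 10⁻², 10⁻¹}, 100 triples — by inner pair-CV mean AUC, with
ties broken toward smaller λ_l + λ_d, then smaller λ_h. Inside repeated CV
(`inner_selection="inner_cv"`) the triple is selected once per repeat by an
inner 3-fold search; a fully nested per-outer-fold search would cost ~10×
more for a hyperparameter-only optimism that never touches test labels.

Reproducibility: each repeat's random stream is derived from
(seed, repeat index) through a counter-based seed sequence, so identical
seeds give bit-identical partitions, fits and AUC vectors.

## Synthetic data

The generators emulate each input class so the entire pipeline is testable
offline; all are pure functions of their seed.

* **Planted associations**: latent factors with i.i.d. standard normal
  entries at a chosen rank; Y marks the top density-quantile of A*B*ᵀ, then
  a fraction of entries is flipped. Defaults (40 × 30, rank 3, density 0.08,
  flip rate 0.02) give ~96 planted positives plus ~24 random flips — a
  deliberately hard, sparse regime. Scoring held-out positives by the latent
  truth itself attains AUC ≈ 0.91 under this noise (flipped-on positives are
  unpredictable), so cross-validated AUCs in the high 0.7s are close to what
  the data support; without flip noise the pipeline reaches ≈ 0.86. What the
  generator does **not** emulate: the block/community structure, scale-free
  degree distributions and curation biases of real association databases,
  or any real correlation between expression similarity and association
  patterns — so passing tests demonstrate correctness and internal
  consistency of the pipeline, not expected performance on real curated
  data.
* **Ontology DAG**: nodes assigned round-robin to layers; each non-root
  node draws 1–2 parents from the layer above, acyclic by construction.
* **Expression profiles**: members of a block share a latent Gaussian
  profile plus independent noise (σ = 0.5), so expression similarity
  recovers the blocks.
* **Line dataset**: n inliers uniform on y = x over x ∈ [−10, 10]
  (symmetric about the origin so the rank-1 model needs no centering), plus
  noise uniform on the bounding square, rejection-sampled outside a band of
  width 10% of the side around the line so noise is genuinely off-subspace.

### Robustness experiment

The point cloud is factored as an n × 2 matrix at rank 1 with no side
kernels, and the recovered direction (the normalized column of B) is
compared with (1,1)/√2 by angular error. For CMF the alternation is power
iteration, i.e. the top right singular vector, which the noise tilts. For
DSCMF the per-row reweighting reduces at rank 1 to soft-thresholding of the
per-point coefficients at λ_h/2: points whose projection onto the current
direction is below threshold drop out of the direction update. With the
symmetric coordinate range, the most off-subspace noise (near the
anti-diagonal corners) has the smallest parallel projection and is exactly
what gets thresholded away. λ_h defaults to 4.0 here so the threshold (2)
matches the width of the noise exclusion band — a geometric choice, made
once. The experiment reports the angular error pair (CMF, DSCMF).

## Numerical and design notes

* Reweighting guard ε = 1e-8 keeps 1/(2‖row‖) finite at zero rows (rows
  collapsed by the sparsity penalty stay at ~ε-scale values).
* Symmetry of computed similarity matrices is enforced to 1e-10 by
  symmetrization after elementwise operations; loaded matrices are checked
  to 1e-8 and symmetrized.
* Candidate rankings break score ties by ascending lncRNA identifier; known
  positives are included by default (matching how ranked prediction tables
  are usually presented) and can be excluded.
* Dense labelled CSVs are written at 17 significant digits and parsed with
  correct rounding, so write → read round-trips are bit-identical.
* Identifier matching is case-sensitive and whitespace-stripped; duplicate
  association pairs collapse with a warning; edge lists are tab-separated,
  matrices comma-separated, all UTF-8.
* Test and acceptance problem sizes (matrices up to 40 × 30, 5 CV repeats,
  ten robustness datasets) were chosen as the smallest instances at which
  every contract is meaningfully exercised; the pipeline itself has no
  size-specific code paths.

## Limitations

* The ontology DAG is taken as given; no OBO/OWL parsing or term mapping.
* Negatives in evaluation are all unknown pairs; if many unknowns are true
  associations, reported AUC underestimates real performance.
* The alternating scheme finds a local optimum; different ranks or seeds can
  give different factors (scores are typically stable).
* Hyperparameter selection inside repeated CV is per-repeat, not per-fold
  (see above); with `inner_selection="fixed"` no selection occurs.
* No GPU or stochastic optimization; intended for matrices up to a few
  thousand on a side.
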