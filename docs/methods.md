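# Methods

## Problem and model

The data are a binary drug-disease adjacency matrix **Y** ∈ {0,1}^(n×m), a
drug-drug chemical similarity matrix **S**_D ∈ [0,1]^(n×n) and a
disease-disease semantic similarity matrix **S**_d ∈ [0,1]^(m×m).  Known
interactions are positives; zeros are *unlabelled*, not negatives.  The model
completes **Y** with a rank-k factorization **Y** ≈ **AB**ᵀ whose factor Gram
matrices are tied to similarity kernels:

J(A,B) = ‖Y − ABᵀ‖²_F + λ_l(‖A‖²_F + ‖B‖²_F) + λ_l‖B‖₂,₁
       + λ_d‖K_D − AAᵀ‖²_F + λ_t‖K_d − BBᵀ‖²_F.

The dual-network terms encode the working assumption that similar drugs
(diseases) occupy nearby latent positions: **K**_D ≈ **AA**ᵀ and
**K**_d ≈ **BB**ᵀ.  The L2,1 penalty on **B** (sum of row norms) zeroes
whole disease rows, pruning diseases whose profiles carry no usable signal.
Scores **AB**ᵀ are used only for ranking and are never clipped.

## Kernels

The Gaussian interaction profile (GIP) kernel scores two drugs by
exp(−γ‖Y(i)−Y(j)‖²) over their adjacency rows (columns for diseases).  The
bandwidth is normalized, γ = γ′ / mean_i ‖Y(i)‖², so that γ′ is scale-free;
default γ′ = 1, the standard convention for interaction-profile kernels.
GIP and measured similarity are fused as K = αS + (1−α)·GIP with default
α = 0.5 (an adjustable trade-off with no privileged value; both boundary
settings are valid models).  Kernels are computed from the WKNKN-imputed
matrix, since imputation is a pre-processing step that precedes the model
proper; computing them from the raw binary matrix is supported by skipping
imputation.

## WKNKN imputation

For each drug row, the K most similar *known* drugs (at least one recorded
interaction; empty profiles are excluded from the pool) contribute their
profiles with weight p^(t−1)·similarity for the t-th nearest neighbour,
normalized by the sum of the K similarities.  The disease side is built
symmetrically on columns, the two estimates are averaged, and the result is
combined with Y by elementwise max — known interactions are never reduced.
Defaults K = 5, p = 0.7, the values at which cross-validated AUC is reported
to stabilize.  Ties in similarity break by ascending index, making the step
deterministic; neighbour similarity uses the raw S_D/S_d (imputation runs
before any kernel exists in the pipeline order).

## Optimization

Factors are initialized from the rank-k truncated SVD of Y,
A = U_k S_k^{1/2}, B = V_k S_k^{1/2}, with a deterministic sign convention
(largest-magnitude entry of each left singular vector positive) so the init
is permutation-equivariant.  Alternating least squares then iterates:

- A-step: A ← (YB + λ_d K_D A)(BᵀB + λ_l I_k + λ_d AᵀA)⁻¹, the k×k system
  solved by factorization, never explicit inversion.
- B-step, row-wise: disease row i solves
  bᵢ(AᵀA + λ_l I_k + λ_t BᵀB + λ_l d_ii I_k) = (YᵀA)ᵢ + λ_t(K_d B)ᵢ with the
  iteratively-reweighted weight d_ii = 1/(2‖bᵢ‖₂) from the current B,
  floored at ‖bᵢ‖ = 1e-8 (the weight is undefined at exactly-zero rows;
  ε-smoothing is the standard IRLS fix).  All rows share one Gram matrix up
  to the scalar d_ii, so a single symmetric eigendecomposition solves every
  row.

The update order is A then B, with d_ii recomputed from the previous B.
Convergence is declared when the relative objective change drops below tol
(default 1e-6), capped at max_iter (default 100) iterations.  A non-finite
objective aborts with the iteration and λ values.

Two numerical caveats are worth stating plainly.  First, these update rules
are the exact block stationarity conditions of J with the dual-network
weights *halved* (the gradient of ‖K − AAᵀ‖² in A is −4(K−AAᵀ)A, while the
rule carries a single λ_d); equivalently, the iteration minimizes J with
λ_d, λ_t read as twice the intended weight.  Since the search grid for these
weights spans four orders of magnitude, the factor is immaterial in
practice, and the rules are kept in their standard printed form.  At
λ_d = λ_t = 0 — a grid point — the fixed point is an exact stationary point
of J as written, which is what the gradient tests verify.  Second, the Gram
terms make the subproblems nonconvex and the A-step is a fixed-point step
(old A appears in the system), so a monotone objective decrease is not
guaranteed in theory; in practice the trace is monotone to ~1e-9 per step on
the problems tested, and rare small increases are logged, not fatal.

The CMF baseline is the same machinery with the L2,1 term removed and raw
similarities in place of fused kernels.

## Hyperparameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| λ_l | Tikhonov + L2,1 weight | 0.5 | middle of the search grid {2⁻², 2⁻¹, 2⁰, 2¹} |
| λ_d, λ_t | drug / disease network weights | 1e-3 | middle of {0, 1e-4, 1e-3, 1e-2, 1e-1} |
| α | kernel fusion weight | 0.5 | equal trust in measured and network similarity |
| γ′ | GIP bandwidth multiplier | 1.0 | standard scale-free normalization |
| k | latent dimension | min(n,m) floored to a multiple of 5, capped at 50 | must be explicit for SVD init; exposed rather than guessed |
| K, p | WKNKN neighbours, decay | 5, 0.7 | reported stability point |
| tol, max_iter | convergence | 1e-6, 100 | relative-change criterion |

`grid_search` tunes (λ_l, λ_d, λ_t) by inner cross-validation on training
data only (default 5 inner folds for runtime; the outer protocol uses 10),
breaking ties toward the lexicographically smallest triple.

## Evaluation protocol

CV-p partitions the known *pairs* uniformly into 10 disjoint folds
(near-equal sizes, seeded).  Per fold, the test pairs are masked to zero and
the entire pipeline — WKNKN, kernels, fit — is re-run on the masked matrix,
so no test information leaks through imputation or the GIP kernels.
Held-out pairs are scored as positives against *all* never-known pairs (the
datasets are heavily unbalanced, which rank-based AUC tolerates; masked
positives are excluded from the negative set).  A repeat's AUC is the mean
over folds; the report gives mean ± sample sd over (default) 10 repeats.
Seeding: per-repeat child seeds are spawned from the master seed via
`numpy.random.SeedSequence.generate_state`, so full runs are bit-for-bit
reproducible.  The knockout ranking (`rank_diseases_for_drug`) removes every
interaction of one drug, refits the pipeline, and ranks that drug's diseases
by score; it uses the hyperparameters handed to it — callers wanting tuned
values should run `grid_search` on the reduced matrix first to avoid
leaking the removed interactions into tuning.

## Synthetic data: what it emulates and what it does not

`generate_synthetic` draws nonnegative latent factors with one dominant
latent axis per row (drugs cluster by "mechanism", diseases by "class"),
thresholds UVᵀ at the (1−density) quantile to hit the target density, flips
entries with the given noise probability, and builds both similarity
matrices as cosine similarity between factor rows — precisely the
S_D ≈ AAᵀ structure the model assumes, which is what makes planted-recovery
tests informative about the optimizer.  Defaults used throughout testing:
n=60, m=40, k_true=4, density=0.05 (the same order as the gold standards'
~1%, feasible at this size), noise=0.

It does *not* emulate real data's long-tailed degree distributions, block
substructure of disease ontologies, systematic biases of 2D-fingerprint
chemical similarity, or text-mining noise in semantic similarity.  Passing
recovery tests therefore certifies the machinery (imputation, kernels,
optimizer, protocol), not performance on any real gold standard; the
published benchmarks must be run through `load_dataset`/`run_cv` directly
for that.

## Degenerate inputs and edge cases

- All-zero Y: the GIP bandwidth is undefined; rejected with advice to run
  WKNKN or supply interactions.
- Drugs/diseases with empty profiles: excluded from the WKNKN neighbour
  pool; their own estimates still form from the other side.
- A neighbourhood with all-zero similarities leaves that estimate at 0 with
  a warning.
- Singular k×k systems (possible at λ_l = 0): raised as a solver error
  advising λ_l > 0.
- Similarity values outside [0,1] are consumed as-is with a warning, never
  rescaled; asymmetry beyond 1e-10 is an error.

## Limitations

- The L2,1 penalty is applied to **B** only (diseases), mirroring the
  method's definition; symmetric regularization of **A** is deliberately out
  of scope.
- No nonnegativity constraints on factors, no stochastic/minibatch solver,
  no multi-kernel learning over α.
- Objective monotonicity is empirical, not proven (see Optimization).
- Grid search re-fits the pipeline per candidate and fold; at the default
  100-point grid on gold-standard-sized matrices this is hours of CPU, so
  tuned runs should subset the grid or parallelize externally.
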