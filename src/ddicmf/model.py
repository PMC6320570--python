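"""Dual-network L2,1-regularized collaborative matrix factorization.

The adjacency matrix Y (n drugs x m diseases) is approximated by A B^T with
low-rank factors A (n x k) and B (m x k).  The objective augments the plain
reconstruction loss with Tikhonov regularization of both factors, an L2,1
penalty on B (sum of row norms — drives whole disease rows to zero), and
dual-network terms tying the factor Gram matrices to the fused similarity
kernels:

    J(A, B) = ||Y - A B^T||_F^2
            + lambda_l (||A||_F^2 + ||B||_F^2) + lambda_l ||B||_{2,1}
            + lambda_d ||K_D - A A^T||_F^2 + lambda_t ||K_d - B B^T||_F^2.

Factors are initialized from the truncated SVD of Y and refined by
alternating least squares.  The A step solves the k x k normal equations

    A <- (Y B + lambda_d K_D A)(B^T B + lambda_l I_k + lambda_d A^T A)^{-1};

the B step is solved row-wise with an iteratively reweighted least-squares
treatment of the L2,1 term: disease row i gets an extra ridge weight
d_ii = 1 / (2 ||b_i||_2) recomputed from the current B (floored at
||b_i|| = 1e-8).  All k x k systems are solved by factorization, never by
explicit inversion.  The plain CMF baseline is the same machinery with the
L2,1 term removed and raw similarities in place of fused kernels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.linalg

from .datasets import ValidationError

__all__ = [
    "HyperParams",
    "FactorPair",
    "FitResult",
    "SolverError",
    "FitError",
    "default_latent_dim",
    "svd_init",
    "l21_norm",
    "objective",
    "update_A",
    "update_B",
    "fit",
    "fit_cmf",
    "predict_scores",
]

logger = logging.getLogger(__name__)

#: floor on ||b_i||_2 in the IRLS weight d_ii = 1/(2 ||b_i||_2)
ROW_NORM_FLOOR = 1e-8


class SolverError(RuntimeError):
    """A k x k normal-equation system was singular."""


class FitError(RuntimeError):
    """The alternating optimization produced a non-finite objective."""


def default_latent_dim(n: int, m: int) -> int:
    """Default k: min(n, m) floored to a multiple of 5, capped at 50."""
    k = min(n, m)
    if k >= 5:
        k -= k % 5
    return max(1, min(k, 50))


@dataclass
class HyperParams:
    """Regularization weights and optimization controls.

    lambda_l weighs the Tikhonov and L2,1 terms, lambda_d / lambda_t the
    drug- and disease-network terms; alpha is the kernel fusion weight and
    gamma_prime the GIP bandwidth multiplier.  k=None resolves to
    `default_latent_dim` at fit time.
    """

    lambda_l: float = 0.5
    lambda_d: float = 1e-3
    lambda_t: float = 1e-3
    alpha: float = 0.5
    gamma_prime: float = 1.0
    k: int | None = None
    max_iter: int = 100
    tol: float = 1e-6

    def __post_init__(self) -> None:
        for name in ("lambda_l", "lambda_d", "lambda_t"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be nonnegative")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValidationError(f"alpha must lie in [0, 1], got {self.alpha}")
        if self.gamma_prime <= 0:
            raise ValidationError("gamma_prime must be positive")
        if self.tol <= 0:
            raise ValidationError("tol must be positive")
        if self.max_iter < 1:
            raise ValidationError("max_iter must be >= 1")

    def resolve_k(self, n: int, m: int) -> int:
        k = self.k if self.k is not None else default_latent_dim(n, m)
        if not 1 <= k <= min(n, m):
            raise ValidationError(f"k={k} must lie in [1, min(n, m)={min(n, m)}]")
        return k


@dataclass
class FactorPair:
    """Latent factors A (n x k, drugs) and B (m x k, diseases)."""

    A: np.ndarray
    B: np.ndarray

    def __post_init__(self) -> None:
        if self.A.ndim != 2 or self.B.ndim != 2 or self.A.shape[1] != self.B.shape[1]:
            raise ValidationError(
                f"factors must share the latent dimension: {self.A.shape} vs {self.B.shape}"
            )
        if not (np.isfinite(self.A).all() and np.isfinite(self.B).all()):
            raise ValidationError("factors contain non-finite entries")

    @property
    def k(self) -> int:
        return self.A.shape[1]


@dataclass
class FitResult:
    factors: FactorPair
    objective_trace: list[float] = field(default_factory=list)
    converged: bool = False
    iterations: int = 0


def _as_array(K) -> np.ndarray:
    """Accept a bare ndarray, SimilarityMatrix (.S) or KernelMatrix (.K)."""
    if hasattr(K, "K"):
        return np.asarray(K.K, dtype=float)
    if hasattr(K, "S"):
        return np.asarray(K.S, dtype=float)
    return np.asarray(K, dtype=float)


def svd_init(Y: np.ndarray, k: int) -> FactorPair:
    """Rank-k SVD split: A = U_k S_k^(1/2), B = V_k S_k^(1/2).

    A B^T is then the best rank-k approximation of Y (Eckart-Young), the
    natural warm start for the alternating updates.
    """
    Y = np.asarray(Y, dtype=float)
    if not 1 <= k <= min(Y.shape):
        raise ValidationError(f"k={k} must lie in [1, min(Y.shape)={min(Y.shape)}]")
    U, s, Vt = np.linalg.svd(Y, full_matrices=False)
    # deterministic sign convention: the largest-|.| entry of each left
    # singular vector is positive, so the init is permutation-equivariant
    for j in range(k):
        if U[np.argmax(np.abs(U[:, j])), j] < 0:
            U[:, j] = -U[:, j]
            Vt[j] = -Vt[j]
    root = np.sqrt(s[:k])
    return FactorPair(A=U[:, :k] * root, B=Vt[:k].T * root)


def l21_norm(B: np.ndarray) -> float:
    """Sum of Euclidean row norms; penalizing it induces row sparsity."""
    return float(np.linalg.norm(np.asarray(B, dtype=float), axis=1).sum())


def objective(
    Y: np.ndarray,
    factors: FactorPair,
    K_D,
    K_d,
    hp: HyperParams,
    include_l21: bool = True,
) -> float:
    """Evaluate the regularized factorization objective J(A, B).

    With include_l21=False this is the plain CMF objective (the baseline).
    """
    Y = np.asarray(Y, dtype=float)
    A, B = factors.A, factors.B
    KD, Kd = _as_array(K_D), _as_array(K_d)
    val = np.linalg.norm(Y - A @ B.T) ** 2
    val += hp.lambda_l * (np.linalg.norm(A) ** 2 + np.linalg.norm(B) ** 2)
    if include_l21:
        val += hp.lambda_l * l21_norm(B)
    val += hp.lambda_d * np.linalg.norm(KD - A @ A.T) ** 2
    val += hp.lambda_t * np.linalg.norm(Kd - B @ B.T) ** 2
    return float(val)


def update_A(Y: np.ndarray, factors: FactorPair, K_D, hp: HyperParams) -> np.ndarray:
    """One alternating step for the drug factor.

    Solves A (B^T B + lambda_l I + lambda_d A^T A) = Y B + lambda_d K_D A
    as a k x k system (the Gram matrix is factorized, not inverted).
    """
    Y = np.asarray(Y, dtype=float)
    A, B = factors.A, factors.B
    KD = _as_array(K_D)
    G = B.T @ B + hp.lambda_l * np.eye(A.shape[1]) + hp.lambda_d * (A.T @ A)
    rhs = Y @ B + hp.lambda_d * (KD @ A)
    try:
        return scipy.linalg.solve(G, rhs.T, assume_a="sym").T
    except (scipy.linalg.LinAlgError, np.linalg.LinAlgError) as exc:
        raise SolverError(
            "singular normal equations in the A update; set lambda_l > 0"
        ) from exc


def update_B(
    Y: np.ndarray,
    factors: FactorPair,
    K_d,
    hp: HyperParams,
    use_l21: bool = True,
) -> np.ndarray:
    """One alternating step for the disease factor, row-wise.

    Row i solves b_i (A^T A + lambda_l I + lambda_t B^T B + lambda_l d_ii I)
    = (Y^T A)_i + lambda_t (K_d B)_i with the IRLS weight
    d_ii = 1/(2 max(||b_i||, 1e-8)) from the current B.  All rows share the
    same Gram matrix up to the scalar d_ii, so one symmetric eigendecomposition
    solves every row.  use_l21=False drops the IRLS weight (CMF baseline).
    """
    Y = np.asarray(Y, dtype=float)
    A, B = factors.A, factors.B
    Kd = _as_array(K_d)
    k = A.shape[1]
    G0 = A.T @ A + hp.lambda_l * np.eye(k) + hp.lambda_t * (B.T @ B)
    rhs = Y.T @ A + hp.lambda_t * (Kd @ B)
    if use_l21:
        row_norms = np.maximum(np.linalg.norm(B, axis=1), ROW_NORM_FLOOR)
        d = hp.lambda_l / (2.0 * row_norms)
    else:
        d = np.zeros(B.shape[0])
    w, Q = np.linalg.eigh((G0 + G0.T) / 2.0)
    denom = w[None, :] + d[:, None]
    if np.min(np.abs(denom)) < 1e-14:
        raise SolverError(
            "singular normal equations in the B update; set lambda_l > 0"
        )
    return (rhs @ Q) / denom @ Q.T


def _alternate(
    Y: np.ndarray,
    K_D,
    K_d,
    hp: HyperParams,
    init: FactorPair | None,
    use_l21: bool,
) -> FitResult:
    Y = np.asarray(Y, dtype=float)
    n, m = Y.shape
    k = hp.resolve_k(n, m)
    factors = init if init is not None else svd_init(Y, k)
    if factors.A.shape != (n, k) or factors.B.shape != (m, k):
        raise ValidationError(
            f"init factors {factors.A.shape}/{factors.B.shape} do not match "
            f"problem ({n}, {m}) at k={k}"
        )

    trace = [objective(Y, factors, K_D, K_d, hp, include_l21=use_l21)]
    converged = False
    it = 0
    for it in range(1, hp.max_iter + 1):
        A_new = update_A(Y, factors, K_D, hp)
        factors = FactorPair(A_new, factors.B)
        B_new = update_B(Y, factors, K_d, hp, use_l21=use_l21)
        factors = FactorPair(factors.A, B_new)
        val = objective(Y, factors, K_D, K_d, hp, include_l21=use_l21)
        if not np.isfinite(val):
            raise FitError(
                f"objective diverged at iteration {it} "
                f"(lambda_l={hp.lambda_l}, lambda_d={hp.lambda_d}, "
                f"lambda_t={hp.lambda_t})"
            )
        prev = trace[-1]
        if val > prev * (1 + 1e-9) + 1e-12:
            # the coupled Gram terms make the subproblems nonconvex; small
            # increases are possible and logged rather than fatal
            logger.debug("objective increased at iteration %d: %g -> %g", it, prev, val)
        trace.append(val)
        if abs(prev - val) <= hp.tol * max(abs(prev), 1e-12):
            converged = True
            break
    return FitResult(factors=factors, objective_trace=trace, converged=converged, iterations=it)


def fit(
    Y: np.ndarray,
    K_D,
    K_d,
    hp: HyperParams | None = None,
    init: FactorPair | None = None,
) -> FitResult:
    """Fit the dual-network L2,1 model by alternating least squares.

    Stops when the relative objective change drops below hp.tol or after
    hp.max_iter iterations; the trace records the objective at init and
    after every iteration.
    """
    return _alternate(Y, K_D, K_d, hp or HyperParams(), init, use_l21=True)


def fit_cmf(
    Y: np.ndarray,
    S_D,
    S_d,
    hp: HyperParams | None = None,
    init: FactorPair | None = None,
) -> FitResult:
    """Plain CMF baseline: no L2,1 term, raw similarities as the networks."""
    return _alternate(Y, S_D, S_d, hp or HyperParams(), init, use_l21=False)


def predict_scores(factors: FactorPair) -> np.ndarray:
    """Score matrix A B^T; scores are used only for ranking, never clipped."""
    return factors.A @ factors.B.T
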