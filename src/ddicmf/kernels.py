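"""Gaussian interaction profile (GIP) kernels and kernel fusion.

A drug's interaction profile is its row of the adjacency matrix Y (its 0/1
vector over diseases); a disease's profile is its column.  The GIP kernel
scores two drugs (or diseases) by a Gaussian of the squared distance between
their profiles,

    GIP(i, j) = exp(-gamma * ||Y(i) - Y(j)||^2),

with the bandwidth normalized by the mean squared profile norm so that
gamma = gamma' / mean_i ||Y(i)||^2 is scale-free.  The network-derived GIP
similarity is then fused with the measured chemical/semantic similarity by a
convex combination K = alpha * S + (1 - alpha) * GIP.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datasets import AlignmentError, InteractionMatrix, SimilarityMatrix, ValidationError

__all__ = ["KernelMatrix", "gip_kernel", "fuse_kernels"]


@dataclass
class KernelMatrix:
    """Fused similarity kernel for one axis of the bipartite network."""

    ids: list[str]
    K: np.ndarray
    axis: str  # "drug" | "disease"
    alpha: float

    def as_similarity(self) -> SimilarityMatrix:
        """View as a plain SimilarityMatrix (e.g. for TSV export)."""
        return SimilarityMatrix(self.ids, self.K)


def gip_kernel(
    im: InteractionMatrix, axis: str = "drug", gamma_prime: float = 1.0
) -> SimilarityMatrix:
    """Gaussian interaction profile kernel over rows (drugs) or columns (diseases).

    Parameters
    ----------
    im
        Interaction matrix, binary or WKNKN-imputed (entries in [0, 1]).
    axis
        "drug" uses rows of Y as profiles, "disease" uses columns.
    gamma_prime
        Dimensionless bandwidth multiplier gamma'; the effective bandwidth is
        gamma = gamma' / mean_i ||Y(i)||^2.
    """
    if axis not in ("drug", "disease"):
        raise ValueError(f"axis must be 'drug' or 'disease', got {axis!r}")
    if gamma_prime <= 0:
        raise ValidationError(f"gamma_prime must be positive, got {gamma_prime}")

    P = im.Y if axis == "drug" else im.Y.T
    ids = im.drug_ids if axis == "drug" else im.disease_ids
    sq = np.einsum("ij,ij->i", P, P)
    mean_sq = sq.mean()
    if mean_sq == 0:
        raise ValidationError(
            "all interaction profiles are empty: the GIP bandwidth "
            "gamma = gamma' / mean ||Y(i)||^2 is undefined; run WKNKN first "
            "or supply a nonzero adjacency matrix"
        )
    gamma = gamma_prime / mean_sq
    d2 = np.maximum(sq[:, None] + sq[None, :] - 2.0 * (P @ P.T), 0.0)
    K = np.exp(-gamma * d2)
    K = (K + K.T) / 2.0
    np.fill_diagonal(K, 1.0)
    return SimilarityMatrix(list(ids), K)


def fuse_kernels(
    S: SimilarityMatrix, G: SimilarityMatrix, alpha: float, axis: str = "drug"
) -> KernelMatrix:
    """Convex combination K = alpha * S + (1 - alpha) * G of measured and GIP similarity."""
    if not 0.0 <= alpha <= 1.0:
        raise ValidationError(f"alpha must lie in [0, 1], got {alpha}")
    if S.S.shape != G.S.shape:
        raise AlignmentError(f"cannot fuse shapes {S.S.shape} and {G.S.shape}")
    if S.ids != G.ids:
        raise AlignmentError("similarity and GIP identifier orders differ")
    K = alpha * S.S + (1.0 - alpha) * G.S
    return KernelMatrix(list(S.ids), K, axis=axis, alpha=alpha)
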