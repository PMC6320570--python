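"""WKNKN: weighted K-nearest-known-neighbour imputation of unknown zeros.

A zero in the adjacency matrix Y is ambiguous — a verified non-association
or simply an untested pair.  WKNKN replaces each unknown 0 with a likelihood
estimate borrowed from the K most similar *known* neighbours (drugs or
diseases with at least one recorded interaction).  The t-th nearest
neighbour (t = 1..K, most similar first) contributes its profile with weight
p^(t-1) * similarity, normalized by the sum of the K similarities; the
drug-side and disease-side estimates are averaged and the result is combined
with Y by an elementwise max, so known interactions are never lost.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .datasets import InteractionMatrix, SimilarityMatrix, ValidationError

__all__ = ["WknknParams", "wknkn"]


@dataclass
class WknknParams:
    """Neighbour count K >= 1 and decay term p in (0, 1]."""

    K: int = 5
    p: float = 0.7

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValidationError(f"K must be >= 1, got {self.K}")
        if not 0.0 < self.p <= 1.0:
            raise ValidationError(f"p must lie in (0, 1], got {self.p}")


def _side_estimate(Y: np.ndarray, S: np.ndarray, K: int, p: float) -> np.ndarray:
    """Profile estimates for every row of Y from its K nearest known rows.

    "Known" rows have at least one interaction; empty rows are excluded from
    the neighbour pool.  Ties in similarity break by ascending index.
    """
    n = Y.shape[0]
    known = np.flatnonzero(Y.sum(axis=1) > 0)
    est = np.zeros_like(Y)
    decay = p ** np.arange(K)
    for i in range(n):
        pool = known[known != i]
        if pool.size == 0:
            continue
        sims = S[i, pool]
        # stable argsort on -sims keeps ascending-index order among ties
        order = np.argsort(-sims, kind="stable")[:K]
        neigh = pool[order]
        s = sims[order]
        denom = s.sum()
        if denom <= 0:
            warnings.warn(
                f"row {i}: all nearest known neighbours have zero similarity; "
                "estimate left at 0",
                stacklevel=3,
            )
            continue
        w = decay[: s.size] * s
        est[i] = (w @ Y[neigh]) / denom
    return est


def wknkn(
    im: InteractionMatrix,
    s_drug: SimilarityMatrix,
    s_disease: SimilarityMatrix,
    params: WknknParams | None = None,
) -> InteractionMatrix:
    """Impute unknown zeros of a binary adjacency matrix.

    Returns a new InteractionMatrix in imputed mode: entries in [0, 1],
    with Y' = max(Y, mean(drug-side estimate, disease-side estimate)).
    """
    params = params or WknknParams()
    if not im.is_binary:
        raise ValidationError("wknkn expects a binary adjacency matrix")
    if s_drug.n != im.n_drugs or s_disease.n != im.n_diseases:
        raise ValidationError(
            f"similarity shapes ({s_drug.n}, {s_disease.n}) do not match "
            f"Y shape {im.Y.shape}"
        )
    if params.K >= im.n_drugs or params.K >= im.n_diseases:
        raise ValidationError(
            f"K={params.K} must be smaller than both axis sizes {im.Y.shape}"
        )

    drug_est = _side_estimate(im.Y, s_drug.S, params.K, params.p)
    dis_est = _side_estimate(im.Y.T, s_disease.S, params.K, params.p).T
    combined = (drug_est + dis_est) / 2.0
    Y_new = np.clip(np.maximum(im.Y, combined), 0.0, 1.0)
    return InteractionMatrix(list(im.drug_ids), list(im.disease_ids), Y_new)
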