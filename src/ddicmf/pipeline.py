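"""End-to-end prediction pipeline: WKNKN -> GIP kernels -> factorization.

Imputation runs first, so the GIP kernels see the likelihood-filled matrix
(empty profiles gain mass and the kernel bandwidth stays defined), then the
fused kernels regularize the alternating factorization of the imputed Y.
"""

from __future__ import annotations

import numpy as np

from .datasets import InteractionMatrix, SimilarityMatrix
from .kernels import fuse_kernels, gip_kernel
from .model import FitResult, HyperParams, fit, predict_scores
from .preprocess import WknknParams, wknkn

__all__ = ["run_pipeline"]


def run_pipeline(
    im: InteractionMatrix,
    s_drug: SimilarityMatrix,
    s_disease: SimilarityMatrix,
    hp: HyperParams | None = None,
    wknkn_params: WknknParams | None = WknknParams(),
) -> tuple[FitResult, np.ndarray]:
    """Run the full method on one dataset; returns (fit result, score matrix).

    wknkn_params=None skips imputation and factorizes the raw binary matrix.
    """
    hp = hp or HyperParams()
    im_work = wknkn(im, s_drug, s_disease, wknkn_params) if wknkn_params else im
    gip_d = gip_kernel(im_work, "drug", hp.gamma_prime)
    gip_t = gip_kernel(im_work, "disease", hp.gamma_prime)
    K_D = fuse_kernels(s_drug, gip_d, hp.alpha, axis="drug")
    K_d = fuse_kernels(s_disease, gip_t, hp.alpha, axis="disease")
    result = fit(im_work.Y, K_D, K_d, hp)
    return result, predict_scores(result.factors)
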