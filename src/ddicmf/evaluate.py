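"""Evaluation: CV-p cross-validation, AUC, grid search and knockout ranking.

CV-p holds out known drug-disease *pairs* (not whole drugs or diseases):
each fold's positive pairs are masked to 0, the full pipeline is refit on
the masked matrix, and the held-out pairs are scored against every
never-known pair.  The datasets are highly unbalanced, so the rank-based
AUC is the headline metric; 10-fold CV is repeated (by default) ten times
and the mean and standard deviation over repeats are reported.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from itertools import product
from typing import Callable, NamedTuple, Sequence

import numpy as np
from scipy.stats import rankdata

from .datasets import InteractionMatrix, SimilarityMatrix, ValidationError
from .model import HyperParams
from .pipeline import run_pipeline
from .preprocess import WknknParams

__all__ = [
    "FoldAssignment",
    "EvalReport",
    "RankedDisease",
    "confusion_rates",
    "auc",
    "cvp_folds",
    "run_cv",
    "grid_search",
    "rank_diseases_for_drug",
    "DEFAULT_GRID",
]

#: the hyperparameter search space: lambda_l in {2^-2..2^1},
#: lambda_d and lambda_t independently in {0, 1e-4, 1e-3, 1e-2, 1e-1}
DEFAULT_GRID: dict[str, tuple[float, ...]] = {
    "lambda_l": (0.25, 0.5, 1.0, 2.0),
    "lambda_d": (0.0, 1e-4, 1e-3, 1e-2, 1e-1),
    "lambda_t": (0.0, 1e-4, 1e-3, 1e-2, 1e-1),
}


@dataclass
class FoldAssignment:
    """Disjoint partition of the known (drug, disease) pairs into test folds."""

    folds: list[np.ndarray]  # each an array of (row, col) index pairs, shape (f, 2)
    seed: int


@dataclass
class EvalReport:
    auc_mean: float
    auc_sd: float
    per_repeat_aucs: list[float]
    best_params: HyperParams
    repeats: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "auc_mean": self.auc_mean,
                "auc_sd": self.auc_sd,
                "per_repeat_aucs": self.per_repeat_aucs,
                "best_params": {
                    "lambda_l": self.best_params.lambda_l,
                    "lambda_d": self.best_params.lambda_d,
                    "lambda_t": self.best_params.lambda_t,
                    "alpha": self.best_params.alpha,
                    "gamma_prime": self.best_params.gamma_prime,
                    "k": self.best_params.k,
                },
                "repeats": self.repeats,
            }
        )


class RankedDisease(NamedTuple):
    disease_id: str
    score: float
    previously_known: bool


def confusion_rates(
    labels: Sequence[int], predictions: Sequence[int]
) -> tuple[float, float]:
    """Sensitivity TP/(TP+FN) and specificity TN/(TN+FP) of binary predictions."""
    y = np.asarray(labels, dtype=int)
    yhat = np.asarray(predictions, dtype=int)
    if y.shape != yhat.shape:
        raise ValidationError(f"length mismatch: {y.shape} labels, {yhat.shape} predictions")
    tp = int(np.sum((y == 1) & (yhat == 1)))
    fn = int(np.sum((y == 1) & (yhat == 0)))
    tn = int(np.sum((y == 0) & (yhat == 0)))
    fp = int(np.sum((y == 0) & (yhat == 1)))
    if tp + fn == 0:
        raise ValidationError("sensitivity undefined: no positive labels")
    if tn + fp == 0:
        raise ValidationError("specificity undefined: no negative labels")
    return tp / (tp + fn), tn / (tn + fp)


def auc(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Rank-based AUC: P(random positive outscores random negative), ties half.

    Equivalent to the area under the ROC curve via the Mann-Whitney statistic.
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("AUC undefined: both classes must be present")
    ranks = rankdata(s)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def cvp_folds(im: InteractionMatrix, n_folds: int = 10, seed: int = 0) -> FoldAssignment:
    """Uniform random partition of known pairs into near-equal test folds."""
    pairs = np.argwhere(im.Y == 1)
    if len(pairs) < n_folds:
        raise ValidationError(
            f"{len(pairs)} known interactions cannot fill {n_folds} folds"
        )
    rng = np.random.default_rng(seed)
    pairs = pairs[rng.permutation(len(pairs))]
    return FoldAssignment(folds=list(np.array_split(pairs, n_folds)), seed=seed)


def _mask_pairs(im: InteractionMatrix, pairs: np.ndarray) -> InteractionMatrix:
    Y = im.Y.copy()
    Y[pairs[:, 0], pairs[:, 1]] = 0.0
    return InteractionMatrix(list(im.drug_ids), list(im.disease_ids), Y)


def _child_seeds(seed: int, count: int) -> list[int]:
    """Deterministic per-repeat seeds spawned from one master seed."""
    states = np.random.SeedSequence(seed).generate_state(count, dtype=np.uint32)
    return [int(s) % (2**31) for s in states]


def run_cv(
    im: InteractionMatrix,
    s_drug: SimilarityMatrix,
    s_disease: SimilarityMatrix,
    hp: HyperParams | None = None,
    n_folds: int = 10,
    repeats: int = 10,
    seed: int = 0,
    wknkn_params: WknknParams | None = WknknParams(),
    score_fn: Callable[..., np.ndarray] | None = None,
) -> EvalReport:
    """CV-p protocol: mask each fold, refit the full pipeline, score held-out pairs.

    Positives of a fold are its masked pairs; negatives are every pair that is
    0 in the *original* matrix (never-known).  Imputation is re-run per fold on
    the masked matrix, so no test information leaks into training.  Each
    repeat's AUC is the mean over its folds; the report carries the mean and
    sample sd over repeats.

    score_fn, if given, replaces the pipeline (signature: masked
    InteractionMatrix, s_drug, s_disease, hp, rng -> score matrix); it exists
    for ablations such as random-score null checks.
    """
    hp = hp or HyperParams()
    if not im.is_binary:
        raise ValidationError("run_cv expects a binary adjacency matrix")
    neg_mask = im.Y == 0
    repeat_aucs: list[float] = []
    for rep_seed in _child_seeds(seed, repeats):
        assignment = cvp_folds(im, n_folds=n_folds, seed=rep_seed)
        fold_aucs = []
        for f, test_pairs in enumerate(assignment.folds):
            im_masked = _mask_pairs(im, test_pairs)
            try:
                if score_fn is None:
                    _, scores = run_pipeline(im_masked, s_drug, s_disease, hp, wknkn_params)
                else:
                    rng = np.random.default_rng(rep_seed + f)
                    scores = score_fn(im_masked, s_drug, s_disease, hp, rng)
            except Exception as exc:
                raise RuntimeError(
                    f"pipeline failed on fold {f} (repeat seed {rep_seed}): {exc}"
                ) from exc
            pos_scores = scores[test_pairs[:, 0], test_pairs[:, 1]]
            neg_scores = scores[neg_mask]
            labels = np.concatenate([np.ones(len(pos_scores)), np.zeros(len(neg_scores))])
            fold_aucs.append(auc(labels, np.concatenate([pos_scores, neg_scores])))
        repeat_aucs.append(float(np.mean(fold_aucs)))
    sd = float(np.std(repeat_aucs, ddof=1)) if repeats > 1 else 0.0
    return EvalReport(
        auc_mean=float(np.mean(repeat_aucs)),
        auc_sd=sd,
        per_repeat_aucs=repeat_aucs,
        best_params=hp,
        repeats=repeats,
    )


def grid_search(
    im: InteractionMatrix,
    s_drug: SimilarityMatrix,
    s_disease: SimilarityMatrix,
    grid: dict[str, Sequence[float]] | None = None,
    n_folds: int = 5,
    seed: int = 0,
    hp_base: HyperParams | None = None,
    wknkn_params: WknknParams | None = WknknParams(),
) -> HyperParams:
    """Pick the (lambda_l, lambda_d, lambda_t) triple maximizing inner-CV AUC.

    Call this on training data only.  Ties break toward the lexicographically
    smallest triple; a single-point grid is returned without running CV.
    """
    grid = dict(DEFAULT_GRID) if grid is None else dict(grid)
    hp_base = hp_base or HyperParams()
    for key in ("lambda_l", "lambda_d", "lambda_t"):
        grid.setdefault(key, (getattr(hp_base, key),))
        if len(grid[key]) == 0:
            raise ValidationError(f"empty grid for {key}")
    combos = sorted(product(grid["lambda_l"], grid["lambda_d"], grid["lambda_t"]))
    if len(combos) == 1:
        ll, ld, lt = combos[0]
        return replace(hp_base, lambda_l=ll, lambda_d=ld, lambda_t=lt)
    best: tuple[float, tuple[float, float, float]] | None = None
    for ll, ld, lt in combos:
        hp = replace(hp_base, lambda_l=ll, lambda_d=ld, lambda_t=lt)
        report = run_cv(
            im, s_drug, s_disease, hp,
            n_folds=n_folds, repeats=1, seed=seed, wknkn_params=wknkn_params,
        )
        # strict > keeps the lexicographically smallest triple on ties
        if best is None or report.auc_mean > best[0]:
            best = (report.auc_mean, (ll, ld, lt))
    ll, ld, lt = best[1]
    return replace(hp_base, lambda_l=ll, lambda_d=ld, lambda_t=lt)


def rank_diseases_for_drug(
    im: InteractionMatrix,
    s_drug: SimilarityMatrix,
    s_disease: SimilarityMatrix,
    hp: HyperParams | None = None,
    drug_id: str = "",
    top_n: int = 10,
    wknkn_params: WknknParams | None = WknknParams(),
) -> list[RankedDisease]:
    """Knockout ranking: remove every interaction of one drug, refit, rank.

    Emulates the simulation protocol for assessing single-drug prediction: the
    drug's row of Y is zeroed, the full pipeline refit, and its diseases
    returned by descending predicted score, each flagged previously-known
    (removed true interaction) or novel.
    """
    i = im.drug_index(drug_id)
    known = im.Y[i] == 1
    if not known.any():
        raise ValidationError(f"drug {drug_id!r} has no known interactions to remove")
    Y = im.Y.copy()
    Y[i, :] = 0.0
    im_reduced = InteractionMatrix(list(im.drug_ids), list(im.disease_ids), Y)
    _, scores = run_pipeline(im_reduced, s_drug, s_disease, hp, wknkn_params)
    order = np.argsort(-scores[i], kind="stable")[:top_n]
    return [
        RankedDisease(im.disease_ids[j], float(scores[i, j]), bool(known[j]))
        for j in order
    ]
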