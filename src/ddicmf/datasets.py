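"""Input/output, domain containers and synthetic fixture generation.

The method operates on three matrices: a binary drug-disease adjacency
matrix ``Y`` (rows = drugs, columns = diseases), a drug-drug chemical
similarity matrix ``S_D`` and a disease-disease semantic similarity matrix
``S_d``.  All three are exchanged as TSV grids with identifier headers:
for ``Y`` the first row holds disease ids and the first column drug ids;
similarity matrices use the same square layout with ids on both axes.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "InteractionMatrix",
    "SimilarityMatrix",
    "DatasetSummary",
    "AlignmentError",
    "MatrixParseError",
    "ValidationError",
    "GenerationError",
    "load_dataset",
    "save_dataset",
    "dataset_summary",
    "generate_synthetic",
]

#: tolerance below which a similarity matrix must equal its transpose
SYMMETRY_TOL = 1e-10


class AlignmentError(ValueError):
    """Shapes or identifier sets of paired matrices do not match."""


class MatrixParseError(ValueError):
    """A TSV cell could not be interpreted as a number."""


class ValidationError(ValueError):
    """An input violates a structural invariant of the method."""


class GenerationError(ValueError):
    """Synthetic-data parameters cannot produce a valid dataset."""


@dataclass
class InteractionMatrix:
    """Bipartite drug-disease adjacency matrix with identifier lists.

    ``Y[i, j] = 1`` records a known therapeutic association between drug
    ``drug_ids[i]`` and disease ``disease_ids[j]``.  After WKNKN imputation
    entries live in ``[0, 1]`` (likelihoods rather than labels); ``is_binary``
    distinguishes the two modes.
    """

    drug_ids: list[str]
    disease_ids: list[str]
    Y: np.ndarray

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=float)
        n, m = self.Y.shape
        if n < 2 or m < 2:
            raise ValidationError(f"need at least 2 drugs and 2 diseases, got {n}x{m}")
        if len(self.drug_ids) != n or len(self.disease_ids) != m:
            raise AlignmentError(
                f"identifier lists ({len(self.drug_ids)}, {len(self.disease_ids)}) "
                f"do not match Y shape {self.Y.shape}"
            )
        for ids, axis in ((self.drug_ids, "drug"), (self.disease_ids, "disease")):
            if len(set(ids)) != len(ids):
                raise ValidationError(f"duplicate {axis} identifiers")
        if not np.isfinite(self.Y).all():
            raise ValidationError("Y contains non-finite entries")
        if self.Y.min() < 0 or self.Y.max() > 1:
            raise ValidationError("Y entries must lie in [0, 1]")

    @property
    def n_drugs(self) -> int:
        return self.Y.shape[0]

    @property
    def n_diseases(self) -> int:
        return self.Y.shape[1]

    @property
    def is_binary(self) -> bool:
        return bool(np.isin(self.Y, (0.0, 1.0)).all())

    def drug_index(self, drug_id: str) -> int:
        try:
            return self.drug_ids.index(drug_id)
        except ValueError:
            raise LookupError(f"unknown drug id {drug_id!r}") from None


@dataclass
class SimilarityMatrix:
    """Square symmetric similarity matrix for one side of the network.

    Entries are dimensionless scores, expected in ``[0, 1]`` with
    self-similarity on the diagonal.  Out-of-range values are tolerated
    with a warning (gold-standard matrices are consumed as distributed,
    never rescaled); asymmetry beyond ``SYMMETRY_TOL`` is an error.
    """

    ids: list[str]
    S: np.ndarray

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        if self.S.ndim != 2 or self.S.shape[0] != self.S.shape[1]:
            raise ValidationError(f"similarity matrix must be square, got {self.S.shape}")
        if len(self.ids) != self.S.shape[0]:
            raise AlignmentError(
                f"{len(self.ids)} identifiers for a {self.S.shape} matrix"
            )
        if not np.isfinite(self.S).all():
            raise ValidationError("similarity matrix contains non-finite entries")
        asym = np.abs(self.S - self.S.T).max()
        if asym > SYMMETRY_TOL:
            raise ValidationError(
                f"similarity matrix asymmetric: max |S - S.T| = {asym:.3g}"
            )
        if self.S.min() < 0 or self.S.max() > 1:
            warnings.warn(
                "similarity values outside [0, 1]; consumed as-is (not rescaled)",
                stacklevel=2,
            )

    @property
    def n(self) -> int:
        return self.S.shape[0]

    def reordered(self, ids: list[str]) -> "SimilarityMatrix":
        """Permute rows/columns to match an authoritative identifier order."""
        if set(ids) != set(self.ids):
            raise AlignmentError("identifier sets differ; cannot reorder")
        pos = {d: i for i, d in enumerate(self.ids)}
        perm = np.array([pos[d] for d in ids])
        return SimilarityMatrix(list(ids), self.S[np.ix_(perm, perm)])


@dataclass
class DatasetSummary:
    n_drugs: int
    n_diseases: int
    n_interactions: int
    sparsity: float

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_drugs": self.n_drugs,
                "n_diseases": self.n_diseases,
                "n_interactions": self.n_interactions,
                "sparsity": self.sparsity,
            }
        )


def _read_grid(path: str | Path) -> pd.DataFrame:
    """Read a TSV grid of numbers with id header row/column, strictly."""
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    values = np.empty(raw.shape, dtype=float)
    for i, row_id in enumerate(raw.index):
        for j, col_id in enumerate(raw.columns):
            cell = raw.iat[i, j]
            try:
                values[i, j] = float(cell)
            except (TypeError, ValueError):
                raise MatrixParseError(
                    f"{path}: non-numeric entry {cell!r} at row {row_id!r}, "
                    f"column {col_id!r}"
                ) from None
    return pd.DataFrame(values, index=raw.index.astype(str), columns=raw.columns.astype(str))


def load_dataset(
    y_path: str | Path, sd_path: str | Path, sdis_path: str | Path
) -> tuple[InteractionMatrix, SimilarityMatrix, SimilarityMatrix]:
    """Load and align the adjacency / similarity triple from TSV files.

    Identifier order in the adjacency file is authoritative; similarity
    files may list the same ids in any order and are permuted to match.
    """
    y = _read_grid(y_path)
    sd = _read_grid(sd_path)
    sdis = _read_grid(sdis_path)

    im = InteractionMatrix(list(y.index), list(y.columns), y.to_numpy())
    for frame, path, ids, label in (
        (sd, sd_path, im.drug_ids, "drug"),
        (sdis, sdis_path, im.disease_ids, "disease"),
    ):
        if frame.shape[0] != len(ids):
            raise AlignmentError(
                f"{path}: {label} similarity is {frame.shape} but Y has "
                f"{len(ids)} {label}s (Y is {im.Y.shape})"
            )
    s_drug = SimilarityMatrix(list(sd.index), sd.to_numpy()).reordered(im.drug_ids)
    s_dis = SimilarityMatrix(list(sdis.index), sdis.to_numpy()).reordered(im.disease_ids)
    return im, s_drug, s_dis


def _write_grid(path: str | Path, values: np.ndarray, index: list[str], columns: list[str]) -> None:
    pd.DataFrame(values, index=index, columns=columns).to_csv(path, sep="\t")


def save_dataset(
    im: InteractionMatrix,
    s_drug: SimilarityMatrix,
    s_disease: SimilarityMatrix,
    y_path: str | Path,
    sd_path: str | Path,
    sdis_path: str | Path,
) -> None:
    """Write the triple in the TSV layout `load_dataset` reads (round-trip safe)."""
    _write_grid(y_path, im.Y, im.drug_ids, im.disease_ids)
    _write_grid(sd_path, s_drug.S, s_drug.ids, s_drug.ids)
    _write_grid(sdis_path, s_disease.S, s_disease.ids, s_disease.ids)


def dataset_summary(im: InteractionMatrix) -> DatasetSummary:
    """Count drugs, diseases and known interactions; sparsity = known / possible."""
    if not im.is_binary:
        raise ValidationError("dataset_summary requires a binary adjacency matrix")
    n_int = int(im.Y.sum())
    return DatasetSummary(
        n_drugs=im.n_drugs,
        n_diseases=im.n_diseases,
        n_interactions=n_int,
        sparsity=n_int / (im.n_drugs * im.n_diseases),
    )


def _cosine_gram(X: np.ndarray) -> np.ndarray:
    """Cosine similarity between rows, symmetrized, unit diagonal."""
    norms = np.linalg.norm(X, axis=1)
    norms[norms == 0] = 1.0
    S = (X / norms[:, None]) @ (X / norms[:, None]).T
    S = np.clip((S + S.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(S, 1.0)
    return S


def generate_synthetic(
    n: int,
    m: int,
    k_true: int,
    density: float,
    noise: float = 0.0,
    seed: int = 0,
) -> tuple[InteractionMatrix, SimilarityMatrix, SimilarityMatrix]:
    """Planted low-rank bipartite dataset with factor-correlated similarities.

    Nonnegative latent factors ``U`` (n x k_true) and ``V`` (m x k_true) are
    drawn with one dominant latent axis per row, so rows cluster by latent
    direction the way drugs cluster by mechanism.  ``Y`` is obtained by
    thresholding ``U V^T`` at the (1 - density) quantile, then each entry is
    flipped independently with probability ``noise``.  Similarities are the
    cosine similarity between factor rows — the structure the model assumes
    (``S_D ~ A A^T``) — mapped to [0, 1] with unit diagonal.

    Deterministic given ``seed``.
    """
    if not 1 <= k_true < min(n, m):
        raise GenerationError(f"need 1 <= k_true < min(n, m); got k_true={k_true}")
    if not 0 < density < 1:
        raise GenerationError(f"density must be in (0, 1), got {density}")
    if not 0 <= noise < 0.5:
        raise GenerationError(f"noise must be in [0, 0.5), got {noise}")

    rng = np.random.default_rng(seed)
    U = rng.exponential(1.0, size=(n, k_true))
    V = rng.exponential(1.0, size=(m, k_true))
    # a dominant latent axis per row sharpens cluster structure
    U[np.arange(n), rng.integers(k_true, size=n)] += 3.0
    V[np.arange(m), rng.integers(k_true, size=m)] += 3.0

    M = U @ V.T
    threshold = np.quantile(M, 1.0 - density)
    Y = (M > threshold).astype(float)
    n_ones = int(Y.sum())
    if n_ones == 0 or n_ones == n * m:
        raise GenerationError(
            f"density {density} infeasible for k_true={k_true}: produced {n_ones} ones"
        )
    if noise > 0:
        flips = rng.random((n, m)) < noise
        Y = np.where(flips, 1.0 - Y, Y)

    drug_ids = [f"drug_{i:04d}" for i in range(n)]
    disease_ids = [f"disease_{j:04d}" for j in range(m)]
    im = InteractionMatrix(drug_ids, disease_ids, Y)
    s_drug = SimilarityMatrix(drug_ids, _cosine_gram(U))
    s_disease = SimilarityMatrix(disease_ids, _cosine_gram(V))
    return im, s_drug, s_disease
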