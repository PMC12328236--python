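"""Gene and perturbation embedding constructors.

Gene embeddings ``G`` are DataFrames indexed by gene identifier
(genes x K); perturbation embeddings ``P`` are DataFrames indexed by
canonical condition string (perturbations x L). All constructors are
deterministic given their inputs and seed; principal-component signs are
fixed by making the largest-magnitude score of each component positive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg

from .data_model import PerturbationLabel, PseudobulkMatrix

__all__ = [
    "EmbeddingPair",
    "UnpredictablePerturbationError",
    "pca_gene_embedding",
    "perturbation_rows",
    "spectral_membership_embedding",
    "reference_pca_perturbation_embedding",
    "random_embedding",
    "load_embedding_tsv",
    "load_membership_edge_list",
    "align_embedding",
]

logger = logging.getLogger(__name__)


class UnpredictablePerturbationError(KeyError):
    """A perturbation's target gene is absent from the embedding rows.

    Callers catch this to restrict the evaluation to predictable
    perturbations.
    """

    def __init__(self, label: PerturbationLabel, missing: str):
        self.label = label
        self.missing = missing
        super().__init__(
            f"cannot embed perturbation {label.canonical_string!r}: "
            f"target {missing!r} is not among the embedding rows"
        )


@dataclass
class EmbeddingPair:
    """A gene embedding G and perturbation embedding P used by the linear model."""

    G: pd.DataFrame  # genes x K
    P: pd.DataFrame  # perturbations x L
    source: str = "pca"

    def __post_init__(self) -> None:
        for name, mat in (("G", self.G), ("P", self.P)):
            if mat.shape[1] < 1:
                raise ValueError(f"{name} must have at least one column")
            if not np.all(np.isfinite(mat.to_numpy())):
                raise ValueError(f"{name} contains non-finite values")

    @property
    def K(self) -> int:
        return self.G.shape[1]

    @property
    def L(self) -> int:
        return self.P.shape[1]


def _fix_component_signs(scores: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-magnitude entry is positive."""
    out = scores.copy()
    for k in range(out.shape[1]):
        col = out[:, k]
        if col[np.argmax(np.abs(col))] < 0:
            out[:, k] = -col
    return out


def pca_gene_embedding(Y_train: PseudobulkMatrix, K: int) -> pd.DataFrame:
    """Gene scores on the top-K principal components of the row-centered matrix.

    Rows (genes) are centered by the per-gene mean across conditions; columns
    are not scaled. Scores are U_K * S_K from the singular value
    decomposition of the centered matrix.
    """
    Y = Y_train.values
    centered = Y - Y.mean(axis=1, keepdims=True)
    max_K = min(centered.shape)
    if not 1 <= K <= max_K:
        raise ValueError(f"K must be in [1, {max_K}], got {K}")
    U, s, _ = np.linalg.svd(centered, full_matrices=False)
    rank = int(np.sum(s > s[0] * max(centered.shape) * np.finfo(float).eps))
    if K > rank:
        raise ValueError(f"K={K} exceeds achievable rank {rank}")
    scores = _fix_component_signs(U[:, :K] * s[:K])
    return pd.DataFrame(
        scores,
        index=pd.Index(Y_train.gene_ids, name="gene"),
        columns=[f"PC{k + 1}" for k in range(K)],
    )


def perturbation_rows(
    G: pd.DataFrame, labels: Sequence[PerturbationLabel]
) -> pd.DataFrame:
    """Perturbation coordinates from a gene-indexed table.

    A single perturbation takes the row of its target gene; a double takes
    the sum of its two target rows; the control maps to the zero row.
    """
    rows = np.zeros((len(labels), G.shape[1]))
    for i, lab in enumerate(labels):
        for target in lab.targets:
            if target not in G.index:
                raise UnpredictablePerturbationError(lab, target)
            rows[i, :] += G.loc[target].to_numpy()
    return pd.DataFrame(
        rows,
        index=pd.Index([lab.canonical_string for lab in labels], name="perturbation"),
        columns=G.columns,
    )


def spectral_membership_embedding(M: pd.DataFrame, L: int) -> pd.DataFrame:
    """Spectral embedding of a binary (perturbation x pathway) membership matrix.

    The affinity is the co-membership matrix M M^T; coordinates are the first
    L eigenvectors of its symmetric normalized Laplacian after removing the
    trivial direction D^{1/2} 1 (removal is exact, by restriction to the
    orthogonal complement, so disconnected-but-nonempty graphs are handled).
    """
    values = M.to_numpy(dtype=float)
    n = values.shape[0]
    if not 1 <= L < n:
        raise ValueError(f"L must be in [1, {n - 1}], got {L}")
    affinity = values @ values.T
    degrees = affinity.sum(axis=1)
    if np.any(degrees <= 0):
        bad = [str(M.index[i]) for i in np.nonzero(degrees <= 0)[0]]
        raise ValueError(f"perturbations with zero pathway membership: {bad}")
    d_inv_sqrt = 1.0 / np.sqrt(degrees)
    laplacian = np.eye(n) - affinity * np.outer(d_inv_sqrt, d_inv_sqrt)
    # orthonormal basis of the complement of the trivial eigenvector
    trivial = np.sqrt(degrees) / np.linalg.norm(np.sqrt(degrees))
    basis = scipy.linalg.null_space(trivial[None, :])  # n x (n-1)
    reduced = basis.T @ laplacian @ basis
    eigvals, eigvecs = scipy.linalg.eigh(reduced)
    coords = basis @ eigvecs[:, :L]
    coords = _fix_component_signs(coords)
    return pd.DataFrame(
        coords,
        index=M.index.copy(),
        columns=[f"SE{k + 1}" for k in range(L)],
    )


def reference_pca_perturbation_embedding(
    Y_ref: PseudobulkMatrix, dim: int = 10
) -> pd.DataFrame:
    """Perturbation coordinates from PCA on the columns of reference data.

    Columns (perturbation mean profiles) are the samples; each reference
    single perturbation gets a row, indexed by its target gene so that it can
    be matched against another dataset's perturbations by target identifier.
    """
    singles = Y_ref.singles
    if not singles:
        raise ValueError("reference data contains no single perturbations")
    cols = np.column_stack([Y_ref.column(lab) for lab in singles])
    centered = cols - cols.mean(axis=1, keepdims=True)
    max_dim = min(centered.shape)
    if not 1 <= dim <= max_dim:
        raise ValueError(f"dim must be in [1, {max_dim}], got {dim}")
    U, s, Vt = np.linalg.svd(centered, full_matrices=False)
    rank = int(np.sum(s > s[0] * max(centered.shape) * np.finfo(float).eps))
    if dim > rank:
        raise ValueError(f"dim={dim} exceeds achievable rank {rank}")
    scores = _fix_component_signs(Vt[:dim, :].T * s[:dim])
    return pd.DataFrame(
        scores,
        index=pd.Index([lab.targets[0] for lab in singles], name="gene"),
        columns=[f"PC{k + 1}" for k in range(dim)],
    )


def random_embedding(ids: Sequence[str], dim: int, seed: int) -> pd.DataFrame:
    """Seeded i.i.d. standard-Normal embedding, one row per identifier."""
    if dim < 1 or len(ids) < 1:
        raise ValueError("need at least one row and one dimension")
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        rng.standard_normal((len(ids), dim)),
        index=pd.Index(list(ids)),
        columns=[f"R{k + 1}" for k in range(dim)],
    )


def load_embedding_tsv(path: str | Path) -> pd.DataFrame:
    """Tab-separated embedding: first column identifier, rest coordinates."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if frame.shape[1] < 1:
        raise ValueError(f"embedding table {path} has no coordinate columns")
    return frame


def align_embedding(
    embedding: pd.DataFrame, ids: Sequence[str], what: str = "embedding"
) -> pd.DataFrame:
    """Inner-join an external embedding against dataset identifiers, logging drops."""
    present = [i for i in ids if i in embedding.index]
    dropped = len(list(ids)) - len(present)
    if dropped:
        logger.info("%s: dropped %d of %d identifiers without a row",
                    what, dropped, len(list(ids)))
    if not present:
        raise ValueError(f"{what}: no identifiers shared with the dataset")
    return embedding.loc[present]


def load_membership_edge_list(path: str | Path) -> pd.DataFrame:
    """Two-column (perturbation, pathway) edge list -> binary membership matrix."""
    edges = pd.read_csv(path, sep="\t", header=None, names=["perturbation", "pathway"])
    matrix = pd.crosstab(edges["perturbation"], edges["pathway"])
    return (matrix > 0).astype(float)
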