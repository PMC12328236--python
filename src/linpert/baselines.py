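"""Baseline prediction models: no-change, mean, additive and the ridge
bilinear linear model, plus a generic ridge decoder from perturbation-level
embeddings.

The linear model solves, for a gene embedding G (genes x K), a perturbation
embedding P (perturbations x L) and row-centered training data Y - b,

    W = (G'G + lambda I)^-1 G' (Y - b) P (P'P + lambda I)^-1,

the closed form of the two-sided ridge normal equations. Fitting is
deterministic; seeds only ever govern data splits, never the solve.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg

from .data_model import (
    DEFAULT_DIALECT,
    LabelDialect,
    PerturbationLabel,
    PseudobulkMatrix,
    parse_condition_label,
)
from .embeddings import EmbeddingPair

__all__ = [
    "PredictionMatrix",
    "LinearModelFit",
    "RidgeDecoderFit",
    "predict_no_change",
    "predict_mean",
    "predict_additive",
    "predict_additive_matrix",
    "fit_linear_model",
    "predict_linear_model",
    "fit_ridge_decoder",
    "predict_ridge_decoder",
]


@dataclass
class PredictionMatrix:
    """Predicted log-expression, read-out genes x test perturbations."""

    values: np.ndarray
    gene_ids: list[str]
    perturbation_labels: list[PerturbationLabel]
    model: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.perturbation_labels)):
            raise ValueError("values shape inconsistent with identifier lists")
        if len(set(self.perturbation_labels)) != len(self.perturbation_labels):
            raise ValueError("perturbation labels are not unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("predictions contain non-finite values")
        self._col_index = {lab: i for i, lab in enumerate(self.perturbation_labels)}

    def column(self, label: PerturbationLabel) -> np.ndarray:
        return self.values[:, self._col_index[label]]

    def subset_genes(self, gene_ids: Sequence[str]) -> "PredictionMatrix":
        row_index = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [row_index[g] for g in gene_ids]
        return PredictionMatrix(
            self.values[rows, :], list(gene_ids),
            list(self.perturbation_labels), self.model,
        )

    def to_frame(self, dialect: LabelDialect = DEFAULT_DIALECT) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=pd.Index(self.gene_ids, name="gene"),
            columns=[lab.to_string(dialect) for lab in self.perturbation_labels],
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def from_tsv(
        cls, path: str | Path, model: str = "",
        dialect: LabelDialect = DEFAULT_DIALECT,
    ) -> "PredictionMatrix":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        labels = [parse_condition_label(str(c), dialect) for c in frame.columns]
        return cls(frame.to_numpy(dtype=float), [str(g) for g in frame.index],
                   labels, model or Path(path).stem)


def predict_no_change(
    pb: PseudobulkMatrix, test: Sequence[PerturbationLabel]
) -> PredictionMatrix:
    """Predict the control expression for every test perturbation."""
    control = pb.control_values
    values = np.tile(control[:, None], (1, len(test)))
    return PredictionMatrix(values, list(pb.gene_ids), list(test), "no-change")


def predict_mean(
    pb_train: PseudobulkMatrix, test: Sequence[PerturbationLabel]
) -> PredictionMatrix:
    """Predict the row mean of the training columns for every test perturbation."""
    b = pb_train.values.mean(axis=1)
    values = np.tile(b[:, None], (1, len(test)))
    return PredictionMatrix(values, list(pb_train.gene_ids), list(test), "mean")


def predict_additive(pb: PseudobulkMatrix, pair: PerturbationLabel) -> np.ndarray:
    """Additive expectation y_A + y_B - y_control for one double perturbation."""
    if not pair.is_double:
        raise ValueError(f"{pair.canonical_string!r} is not a double perturbation")
    a, b_gene = pair.targets
    for single in (PerturbationLabel((a,)), PerturbationLabel((b_gene,))):
        if not pb.has_column(single):
            raise KeyError(
                f"additive prediction for {pair.canonical_string!r} needs "
                f"missing single-perturbation column {single.canonical_string!r}"
            )
    y_a = pb.column(PerturbationLabel((a,)))
    y_b = pb.column(PerturbationLabel((b_gene,)))
    return y_a + y_b - pb.control_values


def predict_additive_matrix(
    pb: PseudobulkMatrix, pairs: Sequence[PerturbationLabel]
) -> PredictionMatrix:
    values = np.column_stack([predict_additive(pb, pair) for pair in pairs])
    return PredictionMatrix(values, list(pb.gene_ids), list(pairs), "additive")


@dataclass
class LinearModelFit:
    """Fitted bilinear ridge model: Y ~ G W P' + b."""

    W: np.ndarray  # K x L
    b: pd.Series  # per read-out gene intercept
    lam: float
    embedding: EmbeddingPair

    def __post_init__(self) -> None:
        if self.W.shape != (self.embedding.K, self.embedding.L):
            raise ValueError("W dimensions do not match the embedding pair")
        if len(self.b) != self.embedding.G.shape[0]:
            raise ValueError("intercept length does not match gene count")
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")


def fit_linear_model(
    Y_train: PseudobulkMatrix,
    emb: EmbeddingPair,
    lam: float = 0.1,
) -> LinearModelFit:
    """Closed-form two-sided ridge solve for W.

    ``emb.G`` must have a row for every Y_train gene and ``emb.P`` a row for
    every non-control Y_train condition (matched by canonical label). The
    intercept b is the row mean over all training columns, control included,
    so that W = 0 reduces exactly to the mean model.
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    G = emb.G.loc[Y_train.gene_ids].to_numpy()
    train_labels = [lab for lab in Y_train.condition_labels if not lab.is_control]
    missing = [lab.canonical_string for lab in train_labels
               if lab.canonical_string not in emb.P.index]
    if missing:
        raise KeyError(f"perturbation embedding lacks rows for {missing}")
    P = emb.P.loc[[lab.canonical_string for lab in train_labels]].to_numpy()
    cols = [Y_train.column(lab) for lab in train_labels]
    Y = np.column_stack(cols)
    b = Y_train.values.mean(axis=1)

    GtG = G.T @ G + lam * np.eye(G.shape[1])
    PtP = P.T @ P + lam * np.eye(P.shape[1])
    if lam == 0:
        for name, mat in (("G", GtG), ("P", PtP)):
            if np.linalg.matrix_rank(mat) < mat.shape[0]:
                raise np.linalg.LinAlgError(
                    f"{name}'{name} is singular at lambda=0; use lambda > 0"
                )
    W = scipy.linalg.solve(GtG, G.T @ (Y - b[:, None]) @ P @
                           np.linalg.inv(PtP), assume_a="pos" if lam > 0 else "gen")
    return LinearModelFit(
        W=W,
        b=pd.Series(b, index=list(Y_train.gene_ids)),
        lam=lam,
        embedding=emb,
    )


def predict_linear_model(
    fit: LinearModelFit, P_test: pd.DataFrame
) -> PredictionMatrix:
    """Predict G W P_test' + b for the perturbations indexing ``P_test``."""
    if P_test.shape[1] != fit.embedding.L:
        raise ValueError(
            f"P_test has {P_test.shape[1]} columns, expected L={fit.embedding.L}"
        )
    G = fit.embedding.G.to_numpy()
    values = G @ fit.W @ P_test.to_numpy().T + fit.b.to_numpy()[:, None]
    labels = [parse_condition_label(str(s)) for s in P_test.index]
    return PredictionMatrix(
        values, list(fit.embedding.G.index), labels, "linear-model"
    )


@dataclass
class RidgeDecoderFit:
    """Per-gene ridge regression from perturbation-level embeddings to expression."""

    coef: np.ndarray  # dims x genes
    intercept: np.ndarray  # genes
    embedding_means: np.ndarray  # dims
    gene_ids: list[str]
    lam: float


def fit_ridge_decoder(
    E_train: pd.DataFrame, Y_train: PseudobulkMatrix, lam: float = 0.1
) -> RidgeDecoderFit:
    """Ridge-regress expression on embedding coordinates, intercept unpenalized.

    ``E_train`` rows (perturbation-level embeddings) must align with
    Y_train's non-control columns by canonical label.
    """
    train_labels = [lab for lab in Y_train.condition_labels if not lab.is_control]
    wanted = [lab.canonical_string for lab in train_labels]
    missing = [s for s in wanted if s not in E_train.index]
    if missing:
        raise KeyError(f"embedding rows missing for training conditions {missing}")
    X = E_train.loc[wanted].to_numpy()
    Y = np.column_stack([Y_train.column(lab) for lab in train_labels])
    x_mean = X.mean(axis=0)
    y_mean = Y.mean(axis=1)
    Xc = X - x_mean
    if lam == 0:
        # minimum-norm least squares; Xc is rank-deficient e.g. for one-hot codings
        coef, *_ = np.linalg.lstsq(Xc, (Y - y_mean[:, None]).T, rcond=None)
    else:
        coef = scipy.linalg.solve(
            Xc.T @ Xc + lam * np.eye(X.shape[1]),
            Xc.T @ (Y - y_mean[:, None]).T,
            assume_a="pos",
        )
    return RidgeDecoderFit(
        coef=coef,
        intercept=y_mean,
        embedding_means=x_mean,
        gene_ids=list(Y_train.gene_ids),
        lam=lam,
    )


def predict_ridge_decoder(
    fit: RidgeDecoderFit, E_test: pd.DataFrame
) -> PredictionMatrix:
    Xc = E_test.to_numpy() - fit.embedding_means
    values = (Xc @ fit.coef).T + fit.intercept[:, None]
    labels = [parse_condition_label(str(s)) for s in E_test.index]
    return PredictionMatrix(values, list(fit.gene_ids), labels, "ridge-decoder")
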