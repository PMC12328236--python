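"""Domain types and dataset handling for perturbation expression data.

Matrices are genes-in-rows throughout; public interfaces index by gene
identifier and by perturbation label, never by raw position.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LabelDialect",
    "PerturbationLabel",
    "SingleCellPerturbationDataset",
    "PseudobulkMatrix",
    "SplitSpec",
    "LabelParseError",
    "DatasetError",
    "parse_condition_label",
    "read_dataset",
    "pseudobulk",
    "top_expressed_genes",
    "make_double_split",
    "make_single_split",
]


class LabelParseError(ValueError):
    """A condition string does not follow the expected label dialect."""


class DatasetError(ValueError):
    """A dataset file violates a structural requirement (for example, no control)."""


@dataclass(frozen=True)
class LabelDialect:
    """String convention for condition labels.

    The default matches the convention used by the distributed Perturb-seq
    datasets: ``"ctrl"`` for the control, ``"G+ctrl"`` for a single
    perturbation and ``"G1+G2"`` for a double perturbation.
    """

    separator: str = "+"
    control_token: str = "ctrl"


DEFAULT_DIALECT = LabelDialect()


@dataclass(frozen=True, order=True)
class PerturbationLabel:
    """A perturbation condition: 0 (control), 1 or 2 target genes.

    ``targets`` is stored sorted lexicographically so that equal conditions
    compare equal regardless of the order in the source string.
    """

    targets: tuple[str, ...]

    def __post_init__(self) -> None:
        ordered = tuple(sorted(self.targets))
        if len(set(ordered)) != len(ordered):
            raise LabelParseError(f"duplicate targets in {self.targets!r}")
        if len(ordered) > 2:
            raise LabelParseError(
                f"at most two target genes supported, got {self.targets!r}"
            )
        object.__setattr__(self, "targets", ordered)

    @property
    def is_control(self) -> bool:
        return len(self.targets) == 0

    @property
    def is_single(self) -> bool:
        return len(self.targets) == 1

    @property
    def is_double(self) -> bool:
        return len(self.targets) == 2

    @property
    def canonical_string(self) -> str:
        return self.to_string(DEFAULT_DIALECT)

    def to_string(self, dialect: LabelDialect = DEFAULT_DIALECT) -> str:
        if self.is_control:
            return dialect.control_token
        if self.is_single:
            return f"{self.targets[0]}{dialect.separator}{dialect.control_token}"
        return dialect.separator.join(self.targets)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.canonical_string


CONTROL = PerturbationLabel(())


def parse_condition_label(
    text: str, dialect: LabelDialect = DEFAULT_DIALECT
) -> PerturbationLabel:
    """Parse a condition string like ``"ctrl"``, ``"KLF1+ctrl"`` or ``"CNN1+CBL"``.

    Control tokens are dropped; the remaining tokens become the (sorted)
    target set. Raises :class:`LabelParseError` for empty tokens or more
    than two targets, naming the offending string.
    """
    if not text:
        raise LabelParseError("empty condition string")
    tokens = text.split(dialect.separator)
    if any(tok == "" for tok in tokens):
        raise LabelParseError(f"empty token in condition string {text!r}")
    targets = tuple(tok for tok in tokens if tok != dialect.control_token)
    if len(targets) > 2:
        raise LabelParseError(
            f"more than two target genes in condition string {text!r}"
        )
    try:
        return PerturbationLabel(targets)
    except LabelParseError as err:
        raise LabelParseError(f"{err} (from condition string {text!r})") from None


@dataclass
class SingleCellPerturbationDataset:
    """Log-expression per cell plus a perturbation label per cell."""

    expression: np.ndarray  # cells x genes
    gene_ids: list[str]
    cell_labels: list[PerturbationLabel]

    def __post_init__(self) -> None:
        self.expression = np.asarray(self.expression, dtype=float)
        if self.expression.ndim != 2:
            raise DatasetError("expression must be a 2-D cells x genes matrix")
        n_cells, n_genes = self.expression.shape
        if n_genes != len(self.gene_ids):
            raise DatasetError("gene_ids length does not match expression columns")
        if n_cells != len(self.cell_labels):
            raise DatasetError("cell_labels length does not match expression rows")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise DatasetError("gene identifiers are not unique")
        if not np.all(np.isfinite(self.expression)):
            raise DatasetError("expression contains non-finite values")

    @property
    def condition_labels(self) -> list[PerturbationLabel]:
        seen: dict[PerturbationLabel, None] = {}
        for lab in self.cell_labels:
            seen.setdefault(lab, None)
        return list(seen)


@dataclass
class PseudobulkMatrix:
    """Mean log-expression per condition (genes x conditions) with a control column."""

    values: np.ndarray
    gene_ids: list[str]
    condition_labels: list[PerturbationLabel]
    control_index: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.condition_labels)):
            raise DatasetError("values shape inconsistent with identifier lists")
        if len(set(self.condition_labels)) != len(self.condition_labels):
            raise DatasetError("condition labels are not unique")
        if len(self.condition_labels) < 2:
            raise DatasetError("need at least two conditions (control + one)")
        n_controls = sum(1 for lab in self.condition_labels if lab.is_control)
        if n_controls != 1:
            raise DatasetError(f"expected exactly one control column, found {n_controls}")
        if not self.condition_labels[self.control_index].is_control:
            raise DatasetError("control_index does not point at the control column")
        self._col_index = {lab: i for i, lab in enumerate(self.condition_labels)}

    # -- lookups -----------------------------------------------------------
    @property
    def control_label(self) -> PerturbationLabel:
        return self.condition_labels[self.control_index]

    @property
    def control_values(self) -> np.ndarray:
        return self.values[:, self.control_index]

    def has_column(self, label: PerturbationLabel) -> bool:
        return label in self._col_index

    def column(self, label: PerturbationLabel) -> np.ndarray:
        try:
            return self.values[:, self._col_index[label]]
        except KeyError:
            raise KeyError(
                f"condition {label.canonical_string!r} not present"
            ) from None

    @property
    def singles(self) -> list[PerturbationLabel]:
        return [lab for lab in self.condition_labels if lab.is_single]

    @property
    def doubles(self) -> list[PerturbationLabel]:
        return [lab for lab in self.condition_labels if lab.is_double]

    # -- reshaping ---------------------------------------------------------
    def subset_genes(self, gene_ids: Sequence[str]) -> "PseudobulkMatrix":
        """Rows for ``gene_ids``, in the given order."""
        row_index = {g: i for i, g in enumerate(self.gene_ids)}
        try:
            rows = [row_index[g] for g in gene_ids]
        except KeyError as err:
            raise KeyError(f"gene {err.args[0]!r} not present") from None
        return PseudobulkMatrix(
            self.values[rows, :], list(gene_ids), list(self.condition_labels),
            self.control_index,
        )

    def subset_conditions(self, labels: Sequence[PerturbationLabel]) -> "PseudobulkMatrix":
        """Columns for ``labels`` (control appended if absent), in the given order."""
        labels = list(labels)
        if not any(lab.is_control for lab in labels):
            labels = labels + [self.control_label]
        cols = [self._col_index[lab] for lab in labels]
        control_index = next(i for i, lab in enumerate(labels) if lab.is_control)
        return PseudobulkMatrix(
            self.values[:, cols], list(self.gene_ids), labels, control_index
        )

    def to_frame(self, dialect: LabelDialect = DEFAULT_DIALECT) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=pd.Index(self.gene_ids, name="gene"),
            columns=[lab.to_string(dialect) for lab in self.condition_labels],
        )

    def to_tsv(self, path: str | Path, dialect: LabelDialect = DEFAULT_DIALECT) -> None:
        self.to_frame(dialect).to_csv(path, sep="\t")

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, dialect: LabelDialect = DEFAULT_DIALECT
    ) -> "PseudobulkMatrix":
        labels = [parse_condition_label(str(c), dialect) for c in frame.columns]
        controls = [i for i, lab in enumerate(labels) if lab.is_control]
        if len(controls) != 1:
            raise DatasetError(
                f"pseudobulk table must have exactly one control column, found {len(controls)}"
            )
        return cls(frame.to_numpy(dtype=float), [str(g) for g in frame.index],
                   labels, controls[0])

    @classmethod
    def from_tsv(
        cls, path: str | Path, dialect: LabelDialect = DEFAULT_DIALECT
    ) -> "PseudobulkMatrix":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        return cls.from_frame(frame, dialect)


@dataclass(frozen=True)
class SplitSpec:
    """A seeded test-train partition of the condition labels."""

    seed: int
    train_labels: tuple[PerturbationLabel, ...]
    test_labels: tuple[PerturbationLabel, ...]
    protocol: Literal["double-holdout", "single-holdout"]

    def __post_init__(self) -> None:
        overlap = set(self.train_labels) & set(self.test_labels)
        if overlap:
            raise ValueError(f"train/test overlap: {sorted(overlap)}")


# ---------------------------------------------------------------------------
# operations


def read_dataset(
    path: str | Path,
    format: Literal["h5ad", "pseudobulk-table"] = "h5ad",
    condition_field: str = "condition",
    layer: str | None = None,
    dialect: LabelDialect = DEFAULT_DIALECT,
    normalize_log1p: bool = False,
) -> SingleCellPerturbationDataset | PseudobulkMatrix:
    """Load a dataset from disk.

    ``h5ad`` yields a :class:`SingleCellPerturbationDataset` (condition labels
    from the per-cell column ``condition_field``); ``pseudobulk-table`` yields
    a :class:`PseudobulkMatrix` directly. Values are passed through unchanged
    unless ``normalize_log1p`` is set, in which case counts are size-factor
    normalized (to the median total) and log1p-transformed.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "pseudobulk-table":
        return PseudobulkMatrix.from_tsv(path, dialect)
    if format != "h5ad":
        raise ValueError(f"unknown format {format!r}")

    import anndata as ad

    adata = ad.read_h5ad(path)
    if condition_field not in adata.obs.columns:
        raise DatasetError(
            f"condition column {condition_field!r} missing from obs "
            f"(available: {list(adata.obs.columns)})"
        )
    matrix = adata.layers[layer] if layer is not None else adata.X
    if hasattr(matrix, "toarray"):
        matrix = matrix.toarray()
    matrix = np.asarray(matrix, dtype=float)
    if normalize_log1p:
        totals = matrix.sum(axis=1)
        if np.any(totals <= 0):
            raise DatasetError("cells with zero total counts cannot be normalized")
        matrix = np.log1p(matrix / totals[:, None] * np.median(totals))
    labels = [parse_condition_label(str(v), dialect) for v in adata.obs[condition_field]]
    if not any(lab.is_control for lab in labels):
        raise DatasetError(
            f"no control condition ({dialect.control_token!r}) found in "
            f"{condition_field!r}"
        )
    return SingleCellPerturbationDataset(
        expression=matrix,
        gene_ids=[str(g) for g in adata.var_names],
        cell_labels=labels,
    )


def pseudobulk(dataset: SingleCellPerturbationDataset) -> PseudobulkMatrix:
    """Per-condition arithmetic mean of the cell-level log-expression."""
    labels = dataset.condition_labels
    if not any(lab.is_control for lab in labels):
        raise DatasetError("dataset has no control condition")
    label_arr = np.array([lab.canonical_string for lab in dataset.cell_labels])
    cols = np.empty((len(dataset.gene_ids), len(labels)))
    for j, lab in enumerate(labels):
        mask = label_arr == lab.canonical_string
        cols[:, j] = dataset.expression[mask, :].mean(axis=0)
    control_index = next(i for i, lab in enumerate(labels) if lab.is_control)
    return PseudobulkMatrix(cols, list(dataset.gene_ids), labels, control_index)


def top_expressed_genes(pb: PseudobulkMatrix, n: int) -> list[str]:
    """The ``n`` genes with the highest control-column expression.

    Ties are broken by smaller row index; if ``n`` exceeds the gene count all
    genes are returned in ranked order.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    control = pb.control_values
    # stable sort on negated values keeps original row order among ties
    order = np.argsort(-control, kind="stable")
    return [pb.gene_ids[i] for i in order[:n]]


def _seeded_holdout(
    candidates: list[PerturbationLabel], test_fraction: float, seed: int
) -> tuple[list[PerturbationLabel], list[PerturbationLabel]]:
    if not 0 < test_fraction <= 1:
        raise ValueError("test_fraction must be in (0, 1]")
    n_test = math.ceil(test_fraction * len(candidates))
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(candidates))
    test_set = {candidates[i] for i in order[:n_test]}
    test = [lab for lab in candidates if lab in test_set]
    rest = [lab for lab in candidates if lab not in test_set]
    return rest, test


def make_double_split(
    pb: PseudobulkMatrix, test_fraction: float = 0.5, seed: int = 0
) -> SplitSpec:
    """All singles + control in train; a seeded fraction of doubles in test."""
    doubles = pb.doubles
    if len(doubles) < 2:
        raise DatasetError("need at least two double perturbations to split")
    train_doubles, test_doubles = _seeded_holdout(doubles, test_fraction, seed)
    train = [lab for lab in pb.condition_labels if not lab.is_double] + train_doubles
    return SplitSpec(seed, tuple(train), tuple(test_doubles), "double-holdout")


def make_single_split(
    pb: PseudobulkMatrix, test_fraction: float = 0.25, seed: int = 0
) -> SplitSpec:
    """Control always in train; a seeded fraction of singles held out."""
    singles = pb.singles
    if len(singles) < 2:
        raise DatasetError("need at least two single perturbations to split")
    train_singles, test_singles = _seeded_holdout(singles, test_fraction, seed)
    train = [
        lab for lab in pb.condition_labels if not lab.is_single
    ] + train_singles
    return SplitSpec(seed, tuple(train), tuple(test_singles), "single-holdout")
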