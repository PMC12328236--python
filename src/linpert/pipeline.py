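"""Benchmark orchestration: configuration, the double- and single-holdout
protocols, and report files.

Both protocols repeat a seeded split a configurable number of times,
fit/ingest every configured model, restrict the evaluation to the
perturbations all models can predict, and write tab-separated reports.
A failure inside one replicate is logged with its seed and aborts that
replicate only.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from . import baselines, embeddings, evaluation, interactions
from .data_model import (
    PerturbationLabel,
    PseudobulkMatrix,
    make_double_split,
    make_single_split,
    pseudobulk,
    read_dataset,
    top_expressed_genes,
)
from .embeddings import EmbeddingPair, UnpredictablePerturbationError

logger = logging.getLogger(__name__)

__all__ = ["BenchmarkConfig", "run_double_benchmark", "run_single_benchmark"]


@dataclass
class BenchmarkConfig:
    """Run plan for one benchmark. Defaults follow the benchmark protocol:
    five replicates for double holdout, two for single holdout, 1,000
    read-out genes, ridge penalty 0.1, K = 10, FDR 5%."""

    dataset: str = ""
    dataset_format: str = "pseudobulk-table"  # or "h5ad"
    condition_field: str = "condition"
    protocol: str = "double-holdout"
    n_replicates: int | None = None  # 5 for doubles, 2 for singles
    test_fraction: float | None = None  # 0.5 for doubles, 0.25 for singles
    top_n_genes: int = 1000
    lam: float = 0.1
    K: int = 10
    fdr_level: float = 0.05
    seeds: list[int] | None = None
    models: list[dict[str, Any]] = field(default_factory=list)
    null_min_values: int = 1000
    n_boot: int = 1000
    output_dir: str = "benchmark_out"

    def __post_init__(self) -> None:
        if self.protocol not in ("double-holdout", "single-holdout"):
            raise ValueError(f"unknown protocol {self.protocol!r}")
        if self.n_replicates is None:
            self.n_replicates = 5 if self.protocol == "double-holdout" else 2
        if self.test_fraction is None:
            self.test_fraction = 0.5 if self.protocol == "double-holdout" else 0.25
        if self.seeds is None:
            self.seeds = list(range(self.n_replicates))
        if len(self.seeds) != self.n_replicates:
            raise ValueError("seeds must have one entry per replicate")
        if not self.models:
            self.models = default_models(self.protocol)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "BenchmarkConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    @property
    def config_hash(self) -> str:
        canon = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]


def default_models(protocol: str) -> list[dict[str, Any]]:
    if protocol == "double-holdout":
        return [
            {"name": "no-change", "type": "no-change"},
            {"name": "additive", "type": "additive"},
        ]
    return [
        {"name": "mean", "type": "mean"},
        {"name": "linear-pca", "type": "linear", "gene_embedding": "pca"},
        {"name": "linear-random", "type": "linear", "gene_embedding": "random"},
    ]


def _load_pseudobulk(config: BenchmarkConfig) -> PseudobulkMatrix:
    data = read_dataset(
        config.dataset,
        format=config.dataset_format,
        condition_field=config.condition_field,
    )
    if isinstance(data, PseudobulkMatrix):
        return data
    return pseudobulk(data)


def _rows_for_labels(
    table: pd.DataFrame, labels: Sequence[PerturbationLabel]
) -> pd.DataFrame:
    """Perturbation rows from a table indexed by label string or by gene id."""
    strings = [lab.canonical_string for lab in labels]
    if all(s in table.index for s in strings):
        return table.loc[strings]
    return embeddings.perturbation_rows(table, labels)


def _linear_predictions(
    pb_train: PseudobulkMatrix,
    train_labels: list[PerturbationLabel],
    test_labels: list[PerturbationLabel],
    mspec: dict[str, Any],
    config: BenchmarkConfig,
    seed: int,
) -> tuple[baselines.PredictionMatrix | None, list[PerturbationLabel]]:
    """Fit one configured linear model; returns (predictions, excluded labels)."""
    K = int(mspec.get("K", config.K))
    gene_source = mspec.get("gene_embedding", "pca")
    if gene_source == "pca":
        G = embeddings.pca_gene_embedding(pb_train, K)
    elif gene_source == "random":
        G = embeddings.random_embedding(pb_train.gene_ids, K, seed=seed + 7919)
    elif gene_source == "external":
        G = embeddings.align_embedding(
            embeddings.load_embedding_tsv(mspec["gene_embedding_path"]),
            pb_train.gene_ids,
            what=f"gene embedding for {mspec['name']}",
        )
    else:
        raise ValueError(f"unknown gene_embedding {gene_source!r}")

    pert_source = mspec.get("perturbation_embedding", "from-genes")
    if pert_source == "from-genes":
        p_table: pd.DataFrame = G
    elif pert_source == "reference":
        ref = read_dataset(
            mspec["reference_path"], format=mspec.get("reference_format", "pseudobulk-table")
        )
        if not isinstance(ref, PseudobulkMatrix):
            ref = pseudobulk(ref)
        p_table = embeddings.reference_pca_perturbation_embedding(
            ref, dim=int(mspec.get("reference_dim", 10))
        )
    elif pert_source == "spectral":
        membership = embeddings.load_membership_edge_list(mspec["membership_path"])
        p_table = embeddings.spectral_membership_embedding(
            membership, L=int(mspec.get("L", config.K))
        )
    elif pert_source == "external":
        p_table = embeddings.load_embedding_tsv(mspec["perturbation_embedding_path"])
    else:
        raise ValueError(f"unknown perturbation_embedding {pert_source!r}")

    def usable(labels: list[PerturbationLabel]) -> tuple[list, list]:
        good, bad = [], []
        for lab in labels:
            try:
                _rows_for_labels(p_table, [lab])
                good.append(lab)
            except (UnpredictablePerturbationError, KeyError):
                bad.append(lab)
        return good, bad

    train_ok, train_bad = usable(train_labels)
    test_ok, test_bad = usable(test_labels)
    if train_bad:
        logger.info(
            "%s: excluded %d training perturbations without embeddings",
            mspec["name"], len(train_bad),
        )
    if test_bad:
        logger.info(
            "%s: excluded %d unpredictable test perturbations: %s",
            mspec["name"], len(test_bad),
            [lab.canonical_string for lab in test_bad],
        )
    if not train_ok or not test_ok:
        logger.warning("%s: nothing predictable; model skipped", mspec["name"])
        return None, test_bad

    P_train = _rows_for_labels(p_table, train_ok)
    emb = EmbeddingPair(G=G, P=P_train, source=f"{gene_source}/{pert_source}")
    fit = baselines.fit_linear_model(
        pb_train.subset_conditions(train_ok), emb, lam=float(mspec.get("lam", config.lam))
    )
    P_test = _rows_for_labels(p_table, test_ok)
    pred = baselines.predict_linear_model(fit, P_test)
    pred.model = mspec["name"]
    return pred, test_bad


def _model_predictions(
    mspec: dict[str, Any],
    pb: PseudobulkMatrix,
    pb_train: PseudobulkMatrix,
    train_labels: list[PerturbationLabel],
    test_labels: list[PerturbationLabel],
    config: BenchmarkConfig,
    seed: int,
) -> baselines.PredictionMatrix | None:
    mtype = mspec.get("type", "linear")
    if mtype == "no-change":
        return baselines.predict_no_change(pb_train, test_labels)
    if mtype == "mean":
        return baselines.predict_mean(pb_train, test_labels)
    if mtype == "additive":
        return baselines.predict_additive_matrix(pb_train, test_labels)
    if mtype == "linear":
        pred, _ = _linear_predictions(
            pb_train, train_labels, test_labels, mspec, config, seed
        )
        return pred
    if mtype == "external":
        pred = baselines.PredictionMatrix.from_tsv(
            mspec["path"], model=mspec["name"]
        )
        keep = [lab for lab in test_labels if lab in pred.perturbation_labels]
        if len(keep) < len(test_labels):
            logger.info(
                "%s: external predictions cover %d of %d test perturbations",
                mspec["name"], len(keep), len(test_labels),
            )
        if not keep:
            return None
        values = np.column_stack([pred.column(lab) for lab in keep])
        pred = baselines.PredictionMatrix(
            values, pred.gene_ids, keep, mspec["name"]
        ).subset_genes(pb.gene_ids)
        return pred
    raise ValueError(f"unknown model type {mtype!r}")


def _write_provenance(out_dir: Path, config: BenchmarkConfig) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out_dir / "config.yaml")
    (out_dir / "provenance.txt").write_text(
        f"config_hash: {config.config_hash}\n"
        f"seeds: {config.seeds}\n"
        f"split_protocol: seeded uniform random holdout\n"
    )


def run_double_benchmark(config: BenchmarkConfig) -> Path:
    """Double-holdout benchmark: L2/Pearson metrics, interaction truth set,
    FDP-TPR curves (the additive model is excluded from curves, as it
    cannot predict a deviation from itself) and class composition tables."""
    out_dir = Path(config.output_dir)
    _write_provenance(out_dir, config)
    pb_full = _load_pseudobulk(config)
    readout = top_expressed_genes(pb_full, config.top_n_genes)
    all_metrics, all_summaries = [], []

    for rep, seed in enumerate(config.seeds):
        rep_dir = out_dir / f"replicate_{rep}_seed_{seed}"
        try:
            _run_double_replicate(
                config, pb_full, readout, seed, rep, rep_dir,
                all_metrics, all_summaries,
            )
        except Exception:
            logger.exception("replicate %d (seed %d) failed; continuing", rep, seed)
    if all_metrics:
        pd.concat(all_metrics).to_csv(out_dir / "metrics_all.tsv", sep="\t", index=False)
        pd.concat(all_summaries).to_csv(out_dir / "summary_all.tsv", sep="\t", index=False)
    return out_dir


def _run_double_replicate(
    config: BenchmarkConfig,
    pb_full: PseudobulkMatrix,
    readout: list[str],
    seed: int,
    rep: int,
    rep_dir: Path,
    all_metrics: list,
    all_summaries: list,
) -> None:
    rep_dir.mkdir(parents=True, exist_ok=True)
    split = make_double_split(pb_full, config.test_fraction, seed)
    train_labels = [lab for lab in split.train_labels if not lab.is_control]
    test_labels = list(split.test_labels)
    pb_readout = pb_full.subset_genes(readout)
    pb_train = pb_readout.subset_conditions(list(split.train_labels))

    predictions: dict[str, baselines.PredictionMatrix] = {}
    for mspec in config.models:
        pred = _model_predictions(
            mspec, pb_readout, pb_train, train_labels, test_labels, config, seed
        )
        if pred is not None:
            predictions[mspec["name"]] = pred

    baseline_name = "additive" if "additive" in predictions else None
    report = evaluation.evaluate_models(
        predictions, pb_readout, baseline=baseline_name,
        n_boot=config.n_boot, seed=seed,
    )
    report.per_perturbation.assign(replicate=rep, seed=seed).to_csv(
        rep_dir / "metrics.tsv", sep="\t", index=False
    )
    report.summary.assign(replicate=rep, seed=seed).to_csv(
        rep_dir / "summary.tsv", sep="\t", index=False
    )
    all_metrics.append(report.per_perturbation.assign(replicate=rep, seed=seed))
    all_summaries.append(report.summary.assign(replicate=rep, seed=seed))

    # interaction truth set on the held-out doubles
    shared = [
        lab for lab in test_labels
        if all(lab in pm.perturbation_labels for pm in predictions.values())
    ]
    additive_pred = baselines.predict_additive_matrix(pb_train, shared)
    deltas = interactions.delta_matrix(pb_readout, additive_pred)
    if deltas.values.size < config.null_min_values:
        logger.warning(
            "replicate %d: only %d delta values (< %d); skipping interaction "
            "analysis", rep, deltas.values.size, config.null_min_values,
        )
        return
    null_fit = interactions.fit_empirical_null(
        deltas.values.ravel(), min_values=config.null_min_values
    )
    calls = interactions.call_interactions(
        deltas, null_fit, config.fdr_level, pb=pb_readout
    )
    calls_frame = interactions.calls_to_frame(calls)
    calls_frame.to_csv(rep_dir / "calls.tsv", sep="\t", index=False)
    n_hits = int(calls_frame["is_interaction"].sum())
    if n_hits == 0:
        logger.warning("replicate %d: no interactions called; no curves", rep)
        return
    u = evaluation.truth_threshold_from_calls(calls)

    curve_dir = rep_dir / "curves"
    curve_dir.mkdir(exist_ok=True)
    class_rows = []
    for name, pred in predictions.items():
        if name == "additive":
            continue  # by definition predicts no deviation from itself
        aligned = baselines.PredictionMatrix(
            np.column_stack([pred.column(lab) for lab in shared]),
            pred.gene_ids, shared, name,
        )
        curve = evaluation.fdp_tpr_curve(aligned, additive_pred, pb_readout, u)
        curve.to_frame().to_csv(curve_dir / f"{name}.tsv", sep="\t", index=False)
        ranking = interactions.rank_predicted_interactions(aligned, additive_pred, D=u)
        top = ranking.head(n_hits).merge(
            calls_frame[["gene", "pair", "class"]], on=["gene", "pair"], how="left"
        )
        comp = top["class"].fillna("none").value_counts()
        for cls, count in comp.items():
            class_rows.append(
                {"model": name, "class": cls, "count": int(count), "of_top": n_hits}
            )
    pd.DataFrame(class_rows).to_csv(
        rep_dir / "classification.tsv", sep="\t", index=False
    )


def run_single_benchmark(config: BenchmarkConfig) -> Path:
    """Single-holdout benchmark: mean baseline plus linear models with the
    configured embedding sources, restricted to the shared predictable
    perturbation set, with bootstrap CIs against the mean baseline."""
    out_dir = Path(config.output_dir)
    _write_provenance(out_dir, config)
    pb_full = _load_pseudobulk(config)
    readout = top_expressed_genes(pb_full, config.top_n_genes)
    all_metrics, all_summaries, all_cis = [], [], []

    for rep, seed in enumerate(config.seeds):
        rep_dir = out_dir / f"replicate_{rep}_seed_{seed}"
        try:
            rep_dir.mkdir(parents=True, exist_ok=True)
            split = make_single_split(pb_full, config.test_fraction, seed)
            train_labels = [lab for lab in split.train_labels if not lab.is_control]
            test_labels = list(split.test_labels)
            pb_readout = pb_full.subset_genes(readout)
            pb_train = pb_readout.subset_conditions(list(split.train_labels))

            predictions: dict[str, baselines.PredictionMatrix] = {}
            for mspec in config.models:
                pred = _model_predictions(
                    mspec, pb_readout, pb_train, train_labels, test_labels,
                    config, seed,
                )
                if pred is not None:
                    predictions[mspec["name"]] = pred
            baseline_name = "mean" if "mean" in predictions else None
            report = evaluation.evaluate_models(
                predictions, pb_readout, baseline=baseline_name,
                n_boot=config.n_boot, seed=seed,
            )
            report.per_perturbation.assign(replicate=rep, seed=seed).to_csv(
                rep_dir / "metrics.tsv", sep="\t", index=False
            )
            report.summary.assign(replicate=rep, seed=seed).to_csv(
                rep_dir / "summary.tsv", sep="\t", index=False
            )
            ci_frame = pd.DataFrame(
                [
                    {
                        "model": ci.model,
                        "baseline": ci.baseline,
                        "statistic": ci.statistic,
                        "low": ci.low,
                        "high": ci.high,
                        "contains_zero": ci.contains_zero,
                        "n_boot": ci.n_boot,
                        "seed": ci.seed,
                    }
                    for ci in report.ci_entries
                ]
            )
            ci_frame.to_csv(rep_dir / "ci.tsv", sep="\t", index=False)
            all_metrics.append(report.per_perturbation.assign(replicate=rep, seed=seed))
            all_summaries.append(report.summary.assign(replicate=rep, seed=seed))
            if not ci_frame.empty:
                all_cis.append(ci_frame.assign(replicate=rep))
        except Exception:
            logger.exception("replicate %d (seed %d) failed; continuing", rep, seed)
    if all_metrics:
        pd.concat(all_metrics).to_csv(out_dir / "metrics_all.tsv", sep="\t", index=False)
        pd.concat(all_summaries).to_csv(out_dir / "summary_all.tsv", sep="\t", index=False)
    if all_cis:
        pd.concat(all_cis).to_csv(out_dir / "ci_all.tsv", sep="\t", index=False)
    return out_dir
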