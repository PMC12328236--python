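"""Prediction-error metrics, FDP-TPR benchmark curves and bootstrap
relative-error confidence intervals."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .baselines import PredictionMatrix
from .data_model import PerturbationLabel, PseudobulkMatrix
from .interactions import InteractionCall

__all__ = [
    "FdpTprCurve",
    "CiEntry",
    "EvaluationReport",
    "l2_error",
    "pearson_delta",
    "fdp_tpr_curve",
    "truth_threshold_from_calls",
    "bootstrap_relative_error",
    "evaluate_models",
]

logger = logging.getLogger(__name__)


def l2_error(
    predicted: np.ndarray,
    observed: np.ndarray,
    gene_ids: Sequence[str] | None = None,
    readout_genes: Sequence[str] | None = None,
) -> float:
    """Euclidean distance between prediction and observation.

    If ``readout_genes`` is given, both vectors (indexed by ``gene_ids``)
    are restricted to that gene list first.
    """
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape:
        raise ValueError("predicted and observed vectors differ in length")
    if readout_genes is not None:
        if gene_ids is None:
            raise ValueError("readout_genes requires gene_ids")
        pos = {g: i for i, g in enumerate(gene_ids)}
        rows = [pos[g] for g in readout_genes]
        predicted = predicted[rows]
        observed = observed[rows]
    return float(np.sqrt(np.sum((predicted - observed) ** 2)))


def pearson_delta(
    predicted: np.ndarray, observed: np.ndarray, control: np.ndarray
) -> float:
    """Pearson correlation of predicted and observed deviations from control.

    Returns NaN (reported as missing, never coerced to 0) if either
    deviation vector has zero variance, for example for the no-change model.
    """
    dp = np.asarray(predicted, dtype=float) - np.asarray(control, dtype=float)
    do = np.asarray(observed, dtype=float) - np.asarray(control, dtype=float)
    if dp.shape != do.shape:
        raise ValueError("vectors differ in length")
    if np.ptp(dp) == 0 or np.ptp(do) == 0:
        logger.info("pearson_delta undefined: zero-variance deviation vector")
        return float("nan")
    return float(np.corrcoef(dp, do)[0, 1])


@dataclass
class FdpTprCurve:
    """Recall of true interactions as a function of the false discovery proportion."""

    u: float  # truth threshold on |observed - additive|
    fdp: np.ndarray  # points after the monotone-envelope transform
    tpr: np.ndarray
    raw_fdp: np.ndarray  # FDP_l, l = 1..N in ranking order
    raw_tpr: np.ndarray
    ordering: np.ndarray  # permutation ranking predicted deviations
    N: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"FDP": self.fdp, "TPR": self.tpr})


def fdp_tpr_curve(
    predicted: PredictionMatrix,
    additive: PredictionMatrix,
    observed: PseudobulkMatrix,
    u: float,
) -> FdpTprCurve:
    """Sweep a threshold over |predicted - additive| and trace (FDP, TPR).

    Truth is 1(|observed - additive| >= u). Entries are ranked by predicted
    deviation magnitude, descending, ties broken by (gene, pair) index; the
    point sequence is sorted by FDP with a running-maximum TPR envelope.
    """
    if list(predicted.gene_ids) != list(additive.gene_ids) or list(
        predicted.perturbation_labels
    ) != list(additive.perturbation_labels):
        raise ValueError("predicted and additive matrices are not aligned")
    obs = np.column_stack(
        [observed.column(lab) for lab in additive.perturbation_labels]
    )
    obs_rows = {g: i for i, g in enumerate(observed.gene_ids)}
    obs = obs[[obs_rows[g] for g in additive.gene_ids], :]

    pred_dev = np.abs(predicted.values - additive.values).ravel()
    truth = (np.abs(obs - additive.values) >= u).ravel()
    n_true = int(truth.sum())
    if n_true == 0:
        raise ValueError(f"no observed deviation reaches the truth threshold u={u}")

    N = pred_dev.size
    ordering = np.argsort(-pred_dev, kind="stable")
    hits = truth[ordering]
    positions = np.arange(1, N + 1)
    raw_tpr = np.cumsum(hits) / n_true
    raw_fdp = np.cumsum(~hits) / positions

    s = np.argsort(raw_fdp, kind="stable")
    fdp = raw_fdp[s]
    tpr = np.maximum.accumulate(raw_tpr[s])
    return FdpTprCurve(
        u=float(u), fdp=fdp, tpr=tpr, raw_fdp=raw_fdp, raw_tpr=raw_tpr,
        ordering=ordering, N=N,
    )


def truth_threshold_from_calls(calls: Sequence[InteractionCall]) -> float:
    """Smallest |delta| among flagged interaction calls."""
    flagged = [abs(c.delta) for c in calls if c.is_interaction]
    if not flagged:
        raise ValueError("no flagged interaction calls; cannot derive a threshold")
    return float(min(flagged))


@dataclass
class CiEntry:
    """Bootstrap confidence interval for mean(e_model / e_baseline - 1)."""

    model: str
    baseline: str
    statistic: float
    low: float
    high: float
    n_boot: int
    seed: int

    @property
    def contains_zero(self) -> bool:
        return self.low <= 0.0 <= self.high

    def __post_init__(self) -> None:
        if not self.low <= self.statistic <= self.high:
            raise ValueError("CI bounds do not bracket the point estimate")


def bootstrap_relative_error(
    errors_model: Sequence[float],
    errors_baseline: Sequence[float],
    n_boot: int = 1000,
    seed: int = 0,
    model: str = "model",
    baseline: str = "baseline",
) -> CiEntry:
    """Percentile 95% CI for the mean per-perturbation error ratio minus 1."""
    em = np.asarray(errors_model, dtype=float)
    eb = np.asarray(errors_baseline, dtype=float)
    if em.shape != eb.shape or em.ndim != 1:
        raise ValueError("paired error vectors must have equal length")
    if np.any(eb <= 0):
        raise ValueError("baseline errors must be strictly positive")
    ratios = em / eb - 1.0
    statistic = float(ratios.mean())
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(ratios), size=(n_boot, len(ratios)))
    boot = ratios[idx].mean(axis=1)
    low, high = np.percentile(boot, [2.5, 97.5])
    low = float(min(low, statistic))
    high = float(max(high, statistic))
    return CiEntry(model, baseline, statistic, low, high, n_boot, seed)


@dataclass
class EvaluationReport:
    """Per-(model, perturbation) metrics plus per-model summaries and CIs."""

    per_perturbation: pd.DataFrame  # model, perturbation, l2, pearson_delta
    summary: pd.DataFrame  # model, mean_l2, mean_pearson_delta, n
    ci_entries: list[CiEntry]
    dropped_perturbations: list[PerturbationLabel]


def evaluate_models(
    predictions: Mapping[str, PredictionMatrix],
    observed: PseudobulkMatrix,
    readout_genes: Sequence[str] | None = None,
    baseline: str | None = None,
    n_boot: int = 1000,
    seed: int = 0,
) -> EvaluationReport:
    """Score every model on the perturbations all models (and the data) share.

    Perturbations lacking any model's prediction are dropped with a logged
    count. If ``baseline`` names one of the models, bootstrap relative-error
    CIs of every other model against it are included.
    """
    if not predictions:
        raise ValueError("no prediction matrices supplied")
    shared: list[PerturbationLabel] | None = None
    union: set[PerturbationLabel] = set()
    for pm in predictions.values():
        present = [
            lab for lab in pm.perturbation_labels if observed.has_column(lab)
        ]
        union |= set(pm.perturbation_labels)
        if shared is None:
            shared = present
        else:
            keep = set(present)
            shared = [lab for lab in shared if lab in keep]
    assert shared is not None
    dropped = sorted(union - set(shared))
    if dropped:
        logger.info(
            "evaluate_models: dropped %d perturbations not shared by all models",
            len(dropped),
        )
    if not shared:
        raise ValueError("no perturbation is shared by all models and the data")

    if readout_genes is None:
        readout_genes = list(observed.gene_ids)
    obs_sub = observed.subset_genes(readout_genes)
    control = obs_sub.control_values

    rows = []
    for name, pm in predictions.items():
        pm_sub = pm.subset_genes(readout_genes)
        for lab in shared:
            pred = pm_sub.column(lab)
            obs = obs_sub.column(lab)
            rows.append(
                {
                    "model": name,
                    "perturbation": lab.canonical_string,
                    "l2": l2_error(pred, obs),
                    "pearson_delta": pearson_delta(pred, obs, control),
                }
            )
    per_pert = pd.DataFrame(rows)
    n_missing = int(per_pert["pearson_delta"].isna().sum())
    if n_missing:
        logger.info("evaluate_models: %d pearson_delta values undefined", n_missing)
    summary = (
        per_pert.groupby("model", sort=False)
        .agg(
            mean_l2=("l2", "mean"),
            mean_pearson_delta=("pearson_delta", "mean"),
            n=("l2", "size"),
        )
        .reset_index()
    )

    ci_entries: list[CiEntry] = []
    if baseline is not None:
        if baseline not in predictions:
            raise KeyError(f"baseline model {baseline!r} not among predictions")
        base_err = (
            per_pert[per_pert["model"] == baseline]
            .set_index("perturbation")["l2"]
        )
        for name in predictions:
            if name == baseline:
                continue
            model_err = (
                per_pert[per_pert["model"] == name]
                .set_index("perturbation")["l2"]
            )
            ci_entries.append(
                bootstrap_relative_error(
                    model_err.loc[base_err.index].to_numpy(),
                    base_err.to_numpy(),
                    n_boot=n_boot,
                    seed=seed,
                    model=name,
                    baseline=baseline,
                )
            )
    return EvaluationReport(per_pert, summary, ci_entries, dropped)
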