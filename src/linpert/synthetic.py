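"""Seeded generator of perturbation datasets with known ground truth.

Condition means are built from the same bilinear family the linear model
fits: a control profile b*, low-rank single-perturbation effects
G* W* p_g* (with p_g* tied to the target gene's row of G*, so unseen
singles are predictable from gene coordinates), additive double means, and
optional planted interaction deviations of stated classes. Cells are the
condition mean plus i.i.d. Normal noise. A single seed fans out to
per-component generators so adding conditions does not perturb existing
draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import (
    CONTROL,
    PerturbationLabel,
    PseudobulkMatrix,
    SingleCellPerturbationDataset,
)
from .interactions import classify_interaction

__all__ = ["SyntheticSpec", "SyntheticTruth", "simulate_dataset", "simulate_delta_mixture"]


@dataclass
class SyntheticSpec:
    n_genes: int = 200
    n_singles: int = 20
    n_doubles: int = 10
    cells_per_condition: int = 1
    true_rank: int = 5
    effect_scale: float = 1.0  # RMS of the low-rank single-perturbation effects
    effect_shift: float = 0.5  # strength of a shared effect direction
    noise_sd: float = 0.1
    interaction_fraction: float = 0.0
    interaction_classes: dict[str, float] = field(
        default_factory=lambda: {"buffering": 0.5, "synergistic": 0.3, "opposite": 0.2}
    )
    interaction_magnitude: float = 6.0  # deviation scale in units of noise_sd
    mismatch_fraction: float = 0.0  # fraction of dense (full-rank) extra effects
    on_infeasible: str = "resample"  # or "error"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_singles, self.cells_per_condition) < 1:
            raise ValueError("counts must be >= 1")
        if self.n_doubles < 0:
            raise ValueError("n_doubles must be >= 0")
        if self.n_singles > self.n_genes:
            raise ValueError("cannot target more genes than exist")
        if self.n_doubles > self.n_singles * (self.n_singles - 1) // 2:
            raise ValueError("more doubles requested than distinct pairs")
        if not 0 <= self.interaction_fraction <= 1:
            raise ValueError("interaction_fraction must be in [0, 1]")
        total = sum(self.interaction_classes.values())
        if self.interaction_classes and abs(total - 1.0) > 1e-9:
            raise ValueError("interaction class weights must sum to 1")
        if self.on_infeasible not in ("resample", "error"):
            raise ValueError("on_infeasible must be 'resample' or 'error'")


@dataclass
class SyntheticTruth:
    G: np.ndarray  # n_genes x K*
    W: np.ndarray  # K* x K*
    P: np.ndarray  # n_singles x K*, rows are true single-perturbation coordinates
    b: np.ndarray  # control profile
    single_targets: list[str]
    planted: pd.DataFrame  # gene, pair, class, deviation
    mean_matrix: PseudobulkMatrix  # noiseless condition means


def _plant_interactions(
    spec: SyntheticSpec,
    rng: np.random.Generator,
    effects: np.ndarray,  # n_genes x n_singles
    gene_ids: list[str],
    pair_targets: list[tuple[int, int]],  # indices into singles
    pair_labels: list[PerturbationLabel],
) -> tuple[np.ndarray, pd.DataFrame]:
    n_genes, _ = effects.shape
    n_pairs = len(pair_targets)
    deviations = np.zeros((n_genes, n_pairs))
    total = n_genes * n_pairs
    n_plant = int(round(spec.interaction_fraction * total))
    records: list[dict] = []
    if n_plant == 0:
        return deviations, pd.DataFrame(
            records, columns=["gene", "pair", "class", "deviation"]
        )

    classes = list(spec.interaction_classes)
    weights = np.array([spec.interaction_classes[c] for c in classes])
    base_mag = spec.interaction_magnitude * spec.noise_sd
    used: set[int] = set()
    attempts = 0
    max_attempts = 200 * n_plant + 1000
    while len(records) < n_plant:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                "could not place the requested interactions; "
                "class weights are incompatible with the single effects"
            )
        flat = int(rng.integers(total))
        if flat in used:
            continue
        gi, pj = divmod(flat, n_pairs)
        ia, ib = pair_targets[pj]
        la, lb = effects[gi, ia], effects[gi, ib]
        cls = classes[int(rng.choice(len(classes), p=weights))]
        add = la + lb
        same_sign = np.sign(la) * np.sign(lb) > 0
        # margins keep both the deviation and the resulting observed LFC at
        # least base_mag away from every class boundary, so neither the
        # detection power nor the class label is eroded by per-cell noise
        if cls == "other":
            feasible = not same_sign
        elif cls == "buffering":
            feasible = same_sign and abs(add) >= 2 * base_mag
        else:
            feasible = same_sign
        feasible = feasible and min(abs(la), abs(lb)) >= base_mag / 2
        if not feasible:
            if spec.on_infeasible == "error":
                raise ValueError(
                    f"class {cls!r} infeasible for single effects "
                    f"({la:.3g}, {lb:.3g}) at gene {gene_ids[gi]}"
                )
            continue
        mag = base_mag * (1.0 + 0.25 * abs(rng.standard_normal()))
        s = np.sign(add) if add != 0 else 1.0
        if cls == "buffering":
            # observed stays in [base_mag, additive), same sign as the singles
            dev = -s * min(mag, abs(add) - base_mag)
        elif cls == "synergistic":
            dev = s * mag
        elif cls == "opposite":
            dev = -s * (mag + abs(add))  # observed flips sign
        else:  # other: any deviation
            dev = rng.choice([-1.0, 1.0]) * mag
        expected = classify_interaction(la, lb, add + dev, add)
        if expected != cls:  # e.g. buffering collapsed onto a boundary
            continue
        used.add(flat)
        deviations[gi, pj] = dev
        records.append(
            {
                "gene": gene_ids[gi],
                "pair": pair_labels[pj].canonical_string,
                "class": cls,
                "deviation": dev,
            }
        )
    return deviations, pd.DataFrame(records)


def simulate_dataset(
    spec: SyntheticSpec,
) -> tuple[SingleCellPerturbationDataset, SyntheticTruth]:
    """Generate a seeded single-cell dataset plus its ground truth."""
    streams = np.random.SeedSequence(spec.seed).spawn(6)
    rng_struct, rng_factors, rng_base, rng_inter, rng_noise, rng_mismatch = (
        np.random.default_rng(s) for s in streams
    )

    gene_ids = [f"G{i:05d}" for i in range(spec.n_genes)]
    target_idx = np.sort(
        rng_struct.choice(spec.n_genes, size=spec.n_singles, replace=False)
    )
    single_targets = [gene_ids[i] for i in target_idx]
    n_pairs_all = spec.n_singles * (spec.n_singles - 1) // 2
    tri_a, tri_b = np.triu_indices(spec.n_singles, k=1)
    chosen = rng_struct.choice(n_pairs_all, size=spec.n_doubles, replace=False)
    pair_targets = [(int(tri_a[c]), int(tri_b[c])) for c in chosen]

    K = spec.true_rank
    G = rng_factors.standard_normal((spec.n_genes, K)) / np.sqrt(K)
    # random orthogonal mixing keeps every latent direction equally strong,
    # so recovery is limited by noise rather than by an accidental near-zero
    # singular value of the mixing matrix
    W, _ = np.linalg.qr(rng_factors.standard_normal((K, K)))
    shift = spec.effect_shift * rng_factors.standard_normal(K)
    P = G[target_idx, :] + shift
    effects = G @ W @ P.T  # n_genes x n_singles
    rms = np.sqrt(np.mean(effects**2))
    if rms > 0 and spec.effect_scale > 0:
        scale = spec.effect_scale / rms
        W = W * scale
        effects = effects * scale
    if spec.mismatch_fraction > 0:
        n_mis = int(round(spec.mismatch_fraction * spec.n_singles))
        which = rng_mismatch.choice(spec.n_singles, size=n_mis, replace=False)
        effects[:, which] += rng_mismatch.normal(
            0.0, spec.effect_scale, size=(spec.n_genes, n_mis)
        )

    b = rng_base.gamma(shape=2.0, scale=1.0, size=spec.n_genes)

    single_labels = [PerturbationLabel((g,)) for g in single_targets]
    pair_labels = [
        PerturbationLabel((single_targets[ia], single_targets[ib]))
        for ia, ib in pair_targets
    ]
    deviations, planted = _plant_interactions(
        spec, rng_inter, effects, gene_ids, pair_targets, pair_labels
    )

    labels = [CONTROL] + single_labels + pair_labels
    means = np.empty((spec.n_genes, len(labels)))
    means[:, 0] = b
    means[:, 1 : 1 + spec.n_singles] = b[:, None] + effects
    for j, (ia, ib) in enumerate(pair_targets):
        means[:, 1 + spec.n_singles + j] = (
            b + effects[:, ia] + effects[:, ib] + deviations[:, j]
        )
    mean_matrix = PseudobulkMatrix(means, gene_ids, labels, 0)

    n_cells = len(labels) * spec.cells_per_condition
    cell_labels = [lab for lab in labels for _ in range(spec.cells_per_condition)]
    expression = np.repeat(means.T, spec.cells_per_condition, axis=0)
    if spec.noise_sd > 0:
        expression = expression + rng_noise.normal(
            0.0, spec.noise_sd, size=(n_cells, spec.n_genes)
        )
    dataset = SingleCellPerturbationDataset(expression, gene_ids, cell_labels)
    truth = SyntheticTruth(
        G=G, W=W, P=P, b=b, single_targets=single_targets,
        planted=planted, mean_matrix=mean_matrix,
    )
    return dataset, truth


def simulate_delta_mixture(
    n: int,
    p0: float,
    null_sd: float = 1.0,
    signal_sd: float = 6.0,
    seed: int = 0,
    signal_shift: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw deviation values from a two-component Normal mixture.

    A fraction ``p0`` is null Normal(0, null_sd^2); the rest is signal. With
    ``signal_shift`` = 0 the signal is Normal(0, signal_sd^2); with a
    positive shift every signal magnitude is at least ``signal_shift`` (a
    random sign times shift + |Normal(0, signal_sd^2)|), which is the shape
    used for guaranteed-magnitude power checks. Returns (values, is_signal).
    """
    if not 0 < p0 <= 1:
        raise ValueError("p0 must be in (0, 1]")
    rng = np.random.default_rng(seed)
    is_signal = rng.random(n) >= p0
    values = rng.normal(0.0, null_sd, size=n)
    n_sig = int(is_signal.sum())
    if n_sig:
        if signal_shift > 0:
            mags = signal_shift + np.abs(rng.normal(0.0, signal_sd, size=n_sig))
            values[is_signal] = rng.choice([-1.0, 1.0], size=n_sig) * mags
        else:
            values[is_signal] = rng.normal(0.0, signal_sd, size=n_sig)
    return values, is_signal
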