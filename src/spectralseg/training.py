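"""Fold construction, epoch sampling and per-fold training.

Cases are split into K equally sized folds (default 7); one model is trained
per held-out fold and the K models are ensembled at inference.  The ``aug``
variant treats the three energy levels as training-time augmentations: every
(case, slice, level) triple is a separate sample, tripling each epoch.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Mapping, NamedTuple, Sequence

import numpy as np

from .architectures import ModelSpec, SegmentationModel, build_model
from .core import SpectralStack, TissueLabelMap, VMI_LEVELS
from .io import layout_channels, normalize_intensity, one_hot
from .losses import masked_dice_loss
from .nn.optim import Adam

logger = logging.getLogger("spectralseg.training")


@dataclass(frozen=True)
class FoldAssignment:
    """Partition of case ids into K folds (sizes differ by at most one)."""

    assignment: dict
    n_folds: int
    seed: int

    def __post_init__(self) -> None:
        folds = set(self.assignment.values())
        if not folds <= set(range(self.n_folds)):
            raise ValueError(f"fold indices {sorted(folds)} outside 0..{self.n_folds - 1}")
        sizes = [len(self.fold_ids(k)) for k in range(self.n_folds)]
        if max(sizes) - min(sizes) > 1:
            raise ValueError(f"fold sizes must differ by at most 1, got {sizes}")

    def fold_ids(self, k: int) -> list:
        return sorted(cid for cid, f in self.assignment.items() if f == k)

    def training_ids(self, held_out: int) -> list:
        if not 0 <= held_out < self.n_folds:
            raise ValueError(f"held-out fold {held_out} outside 0..{self.n_folds - 1}")
        return sorted(cid for cid, f in self.assignment.items() if f != held_out)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=2))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "FoldAssignment":
        payload = json.loads(Path(path).read_text())
        return cls(assignment=payload["assignment"], n_folds=payload["n_folds"],
                   seed=payload["seed"])


def make_folds(case_ids: Sequence, n_folds: int = 7, seed: int = 0) -> FoldAssignment:
    """Randomly partition ``case_ids`` into ``n_folds`` equally sized folds.

    Deterministic given ``seed``; persist the assignment so every model
    variant trains on the same folds.
    """
    ids = list(case_ids)
    if len(set(ids)) != len(ids):
        raise ValueError("case ids must be unique")
    if len(ids) < n_folds:
        raise ValueError(f"need at least {n_folds} cases for {n_folds} folds, got {len(ids)}")
    rng = np.random.default_rng(seed)
    order = [ids[i] for i in rng.permutation(len(ids))]
    assignment = {cid: i % n_folds for i, cid in enumerate(order)}
    return FoldAssignment(assignment=assignment, n_folds=n_folds, seed=int(seed))


class SampleRef(NamedTuple):
    """One training sample: a case, a centre slice, and (for single-energy
    variants) the energy level rendered into the channels."""

    case_id: str
    z: int
    level: int | None


def epoch_sample_plan(variant: str, case_slices: Mapping[str, int],
                      levels: tuple[int, ...] = VMI_LEVELS,
                      baseline_level: int = 70) -> list[SampleRef]:
    """Ordered list of samples making up one epoch.

    aug: one sample per (case, slice, level) — three times the slice count;
    baseline: (case, slice) at the designated level only; fuse/gated:
    (case, slice) with all levels packed into one nine-channel sample.
    """
    plan: list[SampleRef] = []
    if variant == "aug":
        for cid, n in case_slices.items():
            for z in range(n):
                for lv in levels:
                    plan.append(SampleRef(cid, z, lv))
    elif variant == "baseline":
        for cid, n in case_slices.items():
            plan.extend(SampleRef(cid, z, baseline_level) for z in range(n))
    elif variant in ("fuse", "gated"):
        for cid, n in case_slices.items():
            plan.extend(SampleRef(cid, z, None) for z in range(n))
    else:
        raise ValueError(f"unknown variant {variant!r}")
    return plan


@dataclass
class TrainConfig:
    """Training hyper-parameters (config-file exposed)."""

    epochs: int = 100
    batch_size: int = 8
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    seed: int = 0
    baseline_level: int = 70
    k_slices: int = 3
    window: tuple[float, float] = (0.0, 100.0)
    smooth: float = 1e-5
    levels: tuple[int, ...] = VMI_LEVELS

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError(f"epochs must be >= 1, got {self.epochs}")
        if self.batch_size < 1:
            raise ValueError(f"batch_size must be >= 1, got {self.batch_size}")
        if self.optimizer != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")


Cases = Mapping[str, tuple[SpectralStack, TissueLabelMap]]


def _assemble_batch(refs: Sequence[SampleRef], normalized: Mapping[str, SpectralStack],
                    labels: Mapping[str, TissueLabelMap], variant: str,
                    config: TrainConfig) -> tuple[np.ndarray, np.ndarray]:
    xs, ts = [], []
    for ref in refs:
        ps = layout_channels(normalized[ref.case_id], variant, ref.z,
                             k=config.k_slices, level=ref.level, levels=config.levels)
        xs.append(ps.channels)
        ts.append(one_hot(labels[ref.case_id].data[:, :, ref.z]))
    return np.stack(xs), np.stack(ts)


def train_model(cases: Cases, case_ids: Sequence[str], spec: ModelSpec,
                config: TrainConfig, model_seed: int | None = None,
                ) -> tuple[SegmentationModel, list[dict]]:
    """Train one model on ``case_ids`` drawn from ``cases``.

    Returns the trained model and a per-epoch log of the mean masked Dice
    loss.  Fully deterministic given the data and seeds.
    """
    ids = list(case_ids)
    if not ids:
        raise ValueError("empty training partition")
    normalized = {cid: normalize_intensity(cases[cid][0], config.window) for cid in ids}
    labels = {cid: cases[cid][1] for cid in ids}
    case_slices = {cid: normalized[cid].shape[2] for cid in ids}

    plan = epoch_sample_plan(spec.variant, case_slices, levels=config.levels,
                             baseline_level=config.baseline_level)
    if model_seed is None:
        model_seed = int(config.seed)
    model = build_model(spec, seed=model_seed)
    optimizer = Adam(model.parameters(), lr=config.learning_rate)
    rng = np.random.default_rng(np.random.SeedSequence([int(model_seed), 0xA5]))

    log: list[dict] = []
    for epoch in range(config.epochs):
        order = rng.permutation(len(plan))
        losses = []
        for start in range(0, len(plan), config.batch_size):
            refs = [plan[i] for i in order[start:start + config.batch_size]]
            x, t = _assemble_batch(refs, normalized, labels, spec.variant, config)
            optimizer.zero_grad()
            probs = model(x)
            loss = masked_dice_loss(probs, t, smooth=config.smooth)
            loss.backward()
            optimizer.step()
            losses.append(loss.item())
        entry = {"epoch": epoch, "mean_loss": float(np.mean(losses))}
        log.append(entry)
        logger.info("epoch %d/%d mean_loss=%.4f", epoch + 1, config.epochs,
                    entry["mean_loss"])
    return model, log


def train_fold(cases: Cases, folds: FoldAssignment, held_out_fold: int,
               spec: ModelSpec, config: TrainConfig,
               ) -> tuple[SegmentationModel, list[dict]]:
    """Train on every fold except ``held_out_fold``.

    The model's weight-initialisation seed is derived from the config seed
    and the fold index, so the K fold models differ but each is reproducible.
    """
    train_ids = folds.training_ids(held_out_fold)
    missing = [cid for cid in train_ids if cid not in cases]
    if missing:
        raise KeyError(f"cases missing from data: {missing}")
    model_seed = int(np.random.SeedSequence(
        [int(config.seed), int(held_out_fold)]).generate_state(1)[0] & 0x7FFFFFFF)
    logger.info("training fold %d (seed %d): %d cases", held_out_fold,
                model_seed, len(train_ids))
    return train_model(cases, train_ids, spec, config, model_seed=model_seed)


def evaluate_loss(model: SegmentationModel, cases: Cases, case_ids: Sequence[str],
                  config: TrainConfig) -> float:
    """Mean masked Dice loss of ``model`` over all slices of ``case_ids``."""
    spec = model.spec
    normalized = {cid: normalize_intensity(cases[cid][0], config.window)
                  for cid in case_ids}
    labels = {cid: cases[cid][1] for cid in case_ids}
    plan = epoch_sample_plan(spec.variant,
                             {cid: normalized[cid].shape[2] for cid in case_ids},
                             levels=config.levels,
                             baseline_level=config.baseline_level)
    model.eval()
    losses = []
    for start in range(0, len(plan), config.batch_size):
        refs = plan[start:start + config.batch_size]
        x, t = _assemble_batch(refs, normalized, labels, spec.variant, config)
        probs = model(x)
        losses.append(masked_dice_loss(probs, t, smooth=config.smooth).item())
    model.train()
    return float(np.mean(losses))


def write_training_log(log: list[dict], path: str | Path) -> Path:
    """Write the per-epoch loss log as CSV (columns: epoch, mean_loss)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["epoch", "mean_loss"])
        writer.writeheader()
        writer.writerows(log)
    return path
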