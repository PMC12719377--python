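"""Whole-volume slice-wise prediction and fold-ensemble averaging.

The final segmentation of a case is the voxel-wise argmax of the mean of the
per-fold models' probability outputs.  Single-energy variants (baseline/aug)
are evaluated on the 70 keV volume; the three-pathway variants consume all
levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .architectures import SegmentationModel
from .core import N_CLASSES, VMI_LEVELS, SpectralStack, TissueLabelMap
from .io import layout_channels, normalize_intensity


@dataclass
class SegmentationResult:
    """Per-case output: class probabilities, discrete labels, provenance."""

    prob: np.ndarray  # (C, X, Y, Z), sums to 1 per voxel
    labels: TissueLabelMap
    case_id: str = ""
    checkpoints: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.prob.ndim != 4 or self.prob.shape[0] != N_CLASSES:
            raise ValueError(f"prob must be (C, X, Y, Z), got {self.prob.shape}")
        if self.prob.shape[1:] != self.labels.shape:
            raise ValueError("probability and label grids disagree")
        if np.any(self.prob < 0) or not np.allclose(self.prob.sum(axis=0), 1.0,
                                                    atol=1e-4):
            raise ValueError("probabilities must be non-negative and normalized")


def predict_volume(model: SegmentationModel, stack: SpectralStack,
                   window: tuple[float, float] = (0.0, 100.0),
                   baseline_level: int = 70,
                   levels: tuple[int, ...] = VMI_LEVELS,
                   batch_size: int = 16) -> np.ndarray:
    """Predict per-class probabilities for every voxel of ``stack``.

    Every axial slice is assembled with the model variant's channel layout
    (baseline and aug read only the designated single level) and pushed
    through the network; slices are reassembled in order.  Returns a
    ``(C, X, Y, Z)`` float32 volume.
    """
    spec = model.spec
    normalized = normalize_intensity(stack, window)
    depth = normalized.shape[2]
    model.eval()
    planes = []
    for start in range(0, depth, batch_size):
        zs = range(start, min(start + batch_size, depth))
        x = np.stack([
            layout_channels(normalized, spec.variant, z, k=spec.k_slices,
                            level=baseline_level, levels=levels).channels
            for z in zs])
        probs = model(x).data  # (B, C, H, W)
        planes.append(probs)
    model.train()
    out = np.concatenate(planes, axis=0)          # (Z, C, X, Y)
    return np.moveaxis(out, 0, -1).astype(np.float32)  # (C, X, Y, Z)


def ensemble_average(prob_volumes: list[np.ndarray]) -> np.ndarray:
    """Voxel-wise arithmetic mean of probability volumes (stays normalised)."""
    if not prob_volumes:
        raise ValueError("need at least one probability volume")
    shapes = {v.shape for v in prob_volumes}
    if len(shapes) != 1:
        raise ValueError(f"probability volumes disagree on shape: {sorted(shapes)}")
    # extended-precision accumulation keeps the mean independent of the
    # order the fold models are listed in
    out_dtype = np.result_type(*[v.dtype for v in prob_volumes])
    total = np.zeros(prob_volumes[0].shape, dtype=np.longdouble)
    for v in prob_volumes:
        total += v
    return (total / len(prob_volumes)).astype(out_dtype)


def argmax_segmentation(prob: np.ndarray,
                        spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
                        ) -> TissueLabelMap:
    """Discrete segmentation: per-voxel class of maximal probability.

    Ties break toward the lowest class index (numpy argmax convention),
    which keeps the output deterministic.
    """
    prob = np.asarray(prob)
    if prob.ndim != 4:
        raise ValueError(f"expected (C, X, Y, Z) probabilities, got {prob.shape}")
    return TissueLabelMap(np.argmax(prob, axis=0).astype(np.int16), spacing)


def predict_case(models: list[SegmentationModel], stack: SpectralStack,
                 case_id: str = "",
                 window: tuple[float, float] = (0.0, 100.0),
                 baseline_level: int = 70,
                 checkpoints: list | None = None) -> SegmentationResult:
    """Fold-ensemble prediction for one case."""
    probs = [predict_volume(m, stack, window=window, baseline_level=baseline_level)
             for m in models]
    mean_prob = ensemble_average(probs)
    labels = argmax_segmentation(mean_prob, stack.spacing)
    return SegmentationResult(prob=mean_prob, labels=labels, case_id=case_id,
                              checkpoints=list(checkpoints or []))
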