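"""Shared containers and tissue-class conventions.

Volumes follow the nibabel axis convention ``(x, y, z)`` with axial planes
indexed along the third axis.  All physical sizes are millimetres and all
intensities are Hounsfield units (HU) unless stated otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Virtual monoenergetic image (VMI) energy levels used throughout, in keV.
VMI_LEVELS: tuple[int, ...] = (50, 70, 120)

#: Integer label codes for the segmented tissue classes.
BACKGROUND, WM, GM, CSF = 0, 1, 2, 3

CLASS_NAMES: dict[int, str] = {BACKGROUND: "background", WM: "WM", GM: "GM", CSF: "CSF"}

#: Intracranial classes that enter the evaluation (background is excluded).
TISSUE_CLASSES: tuple[int, ...] = (WM, GM, CSF)

N_CLASSES = 4


def _check_spacing(spacing: tuple[float, float, float]) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be three positive lengths in mm, got {spacing}")
    return spacing


@dataclass
class TissueLabelMap:
    """Integer tissue label volume on a regular grid.

    Attributes
    ----------
    data
        3-D integer array with values in ``{0 background, 1 WM, 2 GM, 3 CSF}``.
    spacing
        Voxel edge lengths in mm, one per axis.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"label volume must be 3-D, got shape {self.data.shape}")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError(f"label volume must be integer-typed, got {self.data.dtype}")
        bad = np.setdiff1d(np.unique(self.data), np.arange(N_CLASSES))
        if bad.size:
            raise ValueError(f"label volume contains out-of-range classes {bad.tolist()}")
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def class_counts(self) -> dict[int, int]:
        """Voxel count per class (absent classes included with count 0)."""
        counts = np.bincount(self.data.ravel(), minlength=N_CLASSES)
        return {c: int(counts[c]) for c in range(N_CLASSES)}

    def voxel_volume_ml(self) -> float:
        """Volume of a single voxel in millilitres."""
        return float(np.prod(self.spacing)) / 1000.0


@dataclass
class SpectralStack:
    """Co-registered HU volumes keyed by VMI energy level (keV).

    All member volumes share one grid and voxel spacing; this is the raw
    multi-energy input a segmentation model consumes.
    """

    volumes: dict[int, np.ndarray]
    spacing: tuple[float, float, float] = field(default=(1.0, 1.0, 1.0))

    def __post_init__(self) -> None:
        if not self.volumes:
            raise ValueError("spectral stack needs at least one energy level")
        self.volumes = {int(k): np.asarray(v, dtype=np.float32) for k, v in self.volumes.items()}
        shapes = {v.shape for v in self.volumes.values()}
        if len(shapes) != 1:
            raise ValueError(f"levels disagree on grid shape: {sorted(shapes)}")
        if next(iter(shapes)).__len__() != 3:
            raise ValueError("stack volumes must be 3-D")
        self.spacing = _check_spacing(self.spacing)

    @property
    def levels(self) -> tuple[int, ...]:
        return tuple(sorted(self.volumes))

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.volumes.values())).shape

    def __getitem__(self, level: int) -> np.ndarray:
        try:
            return self.volumes[int(level)]
        except KeyError:
            raise KeyError(f"no {level} keV volume in stack (levels: {self.levels})") from None

    def matches_grid(self, labels: TissueLabelMap) -> bool:
        return self.shape == labels.shape and np.allclose(self.spacing, labels.spacing)
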