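"""Volume I/O, intensity windowing and pseudo-3D sample assembly.

The networks are 2-D with through-plane context: each training or inference
sample is a stack of ``k`` consecutive axial planes per energy level,
ordered level-major (50, 70, 120 keV) and inferior-to-superior within a
level.  Single-energy variants (baseline/aug) use one level's ``k`` planes
(3 channels by default); the three-pathway variants (fuse/gated) use all
levels (9 channels).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

from .core import N_CLASSES, VMI_LEVELS, SpectralStack


class VolumeFormatError(ValueError):
    """Raised when a volume file cannot be parsed."""


def read_volume(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Read a NIfTI volume; returns ``(data, spacing_mm)``."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume file: {path}")
    try:
        img = nib.load(path)
        data = np.asarray(img.dataobj)
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    except Exception as exc:  # nibabel raises several unrelated types
        raise VolumeFormatError(f"cannot read volume {path}: {exc}") from exc
    if data.ndim != 3:
        raise VolumeFormatError(f"{path} is not a 3-D volume (shape {data.shape})")
    return data, spacing


def write_volume(volume: np.ndarray, spacing: tuple[float, float, float],
                 path: str | Path) -> Path:
    """Write a 3-D volume as NIfTI with the spacing in the header."""
    path = Path(path)
    volume = np.asarray(volume)
    if volume.ndim != 3:
        raise ValueError(f"expected a 3-D volume, got shape {volume.shape}")
    if np.issubdtype(volume.dtype, np.integer):
        volume = volume.astype(np.int16)
    else:
        volume = volume.astype(np.float32)
    affine = np.diag([spacing[0], spacing[1], spacing[2], 1.0])
    img = nib.Nifti1Image(volume, affine)
    img.header.set_zooms(spacing)
    img.header.set_data_dtype(volume.dtype)
    nib.save(img, path)
    return path


def normalize_intensity(stack: SpectralStack,
                        window: tuple[float, float] = (0.0, 100.0)) -> SpectralStack:
    """Clip HU values to ``window`` and map them affinely onto [0, 1]."""
    lo, hi = float(window[0]), float(window[1])
    if not lo < hi:
        raise ValueError(f"degenerate intensity window {window}")
    scale = hi - lo
    return SpectralStack(
        {lv: ((np.clip(v, lo, hi) - lo) / scale).astype(np.float32)
         for lv, v in stack.volumes.items()},
        stack.spacing,
    )


def extract_pseudo_slice(volume: np.ndarray, z: int, k: int) -> np.ndarray:
    """``k`` consecutive axial planes centred on ``z`` as a ``(k, H, W)`` array.

    Out-of-range plane indices are replaced by the nearest valid slice
    (edge replication), so the first and last slices still receive ``k``
    channels.
    """
    volume = np.asarray(volume)
    if volume.ndim != 3:
        raise ValueError(f"expected a 3-D volume, got shape {volume.shape}")
    depth = volume.shape[2]
    if k < 1 or k % 2 == 0:
        raise ValueError(f"slice count k must be odd and positive, got {k}")
    if not 0 <= z < depth:
        raise IndexError(f"axial index {z} outside [0, {depth})")
    half = (k - 1) // 2
    idx = np.clip(np.arange(z - half, z + half + 1), 0, depth - 1)
    return np.moveaxis(volume[:, :, idx], 2, 0)


@dataclass
class PseudoSlice:
    """One pseudo-3D sample: ``(k*m, H, W)`` channel planes for a centre slice.

    ``channels`` is ordered level-major then slice; ``target`` (the label
    plane at the centre index) is attached by the training sampler and may
    be ``None`` at inference time.
    """

    channels: np.ndarray
    center_index: int
    levels: tuple[int, ...]
    k: int
    target: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.channels.ndim != 3:
            raise ValueError(f"channels must be (k*m, H, W), got {self.channels.shape}")
        if self.k < 1 or self.k % 2 == 0:
            raise ValueError(f"k must be odd, got {self.k}")
        if self.channels.shape[0] != self.k * len(self.levels):
            raise ValueError(
                f"channel count {self.channels.shape[0]} != k*m = "
                f"{self.k}*{len(self.levels)}")


def layout_channels(stack: SpectralStack, variant: str, z: int, k: int = 3,
                    level: int | None = None,
                    levels: tuple[int, ...] = VMI_LEVELS) -> PseudoSlice:
    """Assemble the channel stack a model variant consumes for slice ``z``.

    baseline/aug use a single designated ``level`` (70 keV unless told
    otherwise); fuse and gated share one layout with all three levels,
    ordered 50, 70, 120 keV.
    """
    if variant in ("baseline", "aug"):
        use_levels = (int(level) if level is not None else 70,)
    elif variant in ("fuse", "gated"):
        use_levels = tuple(levels)
    else:
        raise ValueError(f"unknown variant {variant!r}")
    planes = [extract_pseudo_slice(stack[lv], z, k) for lv in use_levels]
    return PseudoSlice(channels=np.concatenate(planes, axis=0),
                       center_index=z, levels=use_levels, k=k)


def one_hot(label_plane: np.ndarray, n_classes: int = N_CLASSES) -> np.ndarray:
    """Per-class indicator planes ``(C, H, W)``; planes sum to 1 everywhere."""
    label_plane = np.asarray(label_plane)
    bad = np.setdiff1d(np.unique(label_plane), np.arange(n_classes))
    if bad.size:
        raise ValueError(f"labels outside [0, {n_classes}): {bad.tolist()}")
    out = np.zeros((n_classes,) + label_plane.shape, dtype=np.float32)
    for c in range(n_classes):
        out[c] = label_plane == c
    return out
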