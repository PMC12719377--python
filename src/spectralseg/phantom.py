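"""Synthetic head phantoms and their multi-energy CT rendering.

The phantom replaces a patient cohort: a nested ellipsoidal head (outer CSF
shell, folded cortical grey-matter ribbon, white-matter core, CSF-filled
ventricle) is voxelised onto a regular grid and rendered into noisy virtual
monoenergetic images (VMIs) at 50, 70 and 120 keV.  The spectral model
encodes the two physical trends that motivate multi-energy input: grey/white
contrast falls with increasing keV while image noise also falls with keV.

Cortical folding is modelled as a sinusoidal radial perturbation of the
GM/WM interface in spherical angle — a deliberately simple stand-in for
sulci/fissures that still produces thin, overlap-sensitive structures.
There is no skull: only the intracranial classes are segmented, so
background abuts the CSF shell directly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import __version__ as _generator_version
from .core import BACKGROUND, CSF, GM, WM, SpectralStack, TissueLabelMap
from .io import read_volume, write_volume


class DegenerateGeometryError(ValueError):
    """Raised when a geometry collapses a tissue class to zero voxels."""


_JITTERED_FIELDS = (
    "head_semi_axes",
    "csf_shell_thickness",
    "cortex_thickness",
    "ventricle_semi_axes",
    "cortical_fold_amplitude",
    "cortical_fold_frequency",
)


@dataclass(frozen=True)
class PhantomGeometry:
    """Head phantom geometry; all lengths in mm.

    ``jitter_fractions`` gives, per field, the half-width of the uniform
    relative perturbation applied per case (default +-10%), which creates the
    inter-case variance cross-validation and jackknifing act on.
    """

    head_semi_axes: tuple[float, float, float] = (75.0, 85.0, 55.0)
    csf_shell_thickness: float = 6.0
    cortex_thickness: float = 12.0
    ventricle_semi_axes: tuple[float, float, float] = (18.0, 12.0, 10.0)
    cortical_fold_amplitude: float = 6.0
    cortical_fold_frequency: float = 6.0
    jitter_fractions: dict = field(
        default_factory=lambda: {name: 0.10 for name in _JITTERED_FIELDS})

    def __post_init__(self) -> None:
        a = self.head_semi_axes
        if len(a) != 3 or any(x <= 0 for x in a):
            raise ValueError(f"head_semi_axes must be three positive lengths, got {a}")
        if self.csf_shell_thickness <= 0 or self.cortex_thickness <= 0:
            raise ValueError("shell and cortex thicknesses must be positive")
        if self.cortex_thickness + self.csf_shell_thickness >= min(a):
            raise ValueError(
                "cortex_thickness + csf_shell_thickness must be smaller than the "
                f"smallest head semi-axis ({min(a)} mm)")
        wm = self.wm_semi_axes
        v = self.ventricle_semi_axes
        if len(v) != 3 or any(x <= 0 for x in v):
            raise ValueError(f"ventricle_semi_axes must be three positive lengths, got {v}")
        if any(vv >= ww for vv, ww in zip(v, wm)):
            raise ValueError(
                f"ventricles {v} must lie strictly inside the WM core {wm}")
        if self.cortical_fold_amplitude < 0 or self.cortical_fold_frequency < 0:
            raise ValueError("fold amplitude and frequency must be non-negative")
        unknown = set(self.jitter_fractions) - set(_JITTERED_FIELDS)
        if unknown:
            raise ValueError(f"unknown jitter fields {sorted(unknown)}")

    @property
    def gm_semi_axes(self) -> tuple[float, float, float]:
        t = self.csf_shell_thickness
        return tuple(x - t for x in self.head_semi_axes)

    @property
    def wm_semi_axes(self) -> tuple[float, float, float]:
        t = self.csf_shell_thickness + self.cortex_thickness
        return tuple(x - t for x in self.head_semi_axes)

    def jittered(self, rng: np.random.Generator) -> "PhantomGeometry":
        """Per-case geometry: each field scaled by ``1 + U(-f, f)``."""
        changes: dict = {}
        for name in _JITTERED_FIELDS:  # fixed order => reproducible draws
            f = self.jitter_fractions.get(name, 0.0)
            value = getattr(self, name)
            if isinstance(value, tuple):
                scale = 1.0 + rng.uniform(-f, f, size=3)
                changes[name] = tuple(float(v * s) for v, s in zip(value, scale))
            else:
                changes[name] = float(value * (1.0 + rng.uniform(-f, f)))
        return replace(self, **changes)


@dataclass(frozen=True)
class SpectralModel:
    """Mean HU per (tissue class, keV level) plus per-level noise.

    Defaults satisfy the physical trends of virtual monoenergetic imaging:
    GM-WM contrast strictly decreases with keV, noise strictly decreases
    with keV, and CSF < WM < GM at every level.  The numbers themselves are
    plausible brain-window values and are fully configurable.
    """

    hu_table: dict = field(default_factory=lambda: {
        50: {BACKGROUND: -1000.0, CSF: 7.0, WM: 31.0, GM: 44.0},
        70: {BACKGROUND: -1000.0, CSF: 9.0, WM: 29.0, GM: 38.0},
        120: {BACKGROUND: -1000.0, CSF: 10.0, WM: 28.0, GM: 34.0},
    })
    noise_sd: dict = field(default_factory=lambda: {50: 6.0, 70: 4.0, 120: 3.0})

    def __post_init__(self) -> None:
        levels = self.levels
        if set(self.noise_sd) != set(self.hu_table):
            raise ValueError("hu_table and noise_sd must cover the same keV levels")
        for lv in levels:
            row = self.hu_table[lv]
            missing = {CSF, WM, GM} - set(row)
            if missing:
                raise ValueError(f"hu_table at {lv} keV missing classes {sorted(missing)}")
            if not (row[CSF] < row[WM] < row[GM]):
                raise ValueError(
                    f"need CSF < WM < GM at every level; violated at {lv} keV: {row}")
        contrasts = [self.hu_table[lv][GM] - self.hu_table[lv][WM] for lv in levels]
        if not all(a > b for a, b in zip(contrasts, contrasts[1:])):
            raise ValueError(
                f"GM-WM contrast must strictly decrease with keV, got {contrasts}")
        sds = [self.noise_sd[lv] for lv in levels]
        if any(s < 0 for s in sds):
            raise ValueError("noise sd must be non-negative")
        if not all(a > b or (a == b == 0) for a, b in zip(sds, sds[1:])):
            raise ValueError(f"noise sd must strictly decrease with keV, got {sds}")

    @property
    def levels(self) -> tuple[int, ...]:
        return tuple(sorted(self.hu_table))

    def hu_lookup(self, level: int) -> np.ndarray:
        """HU value per class code at ``level``, indexable by the label map."""
        if level not in self.hu_table:
            raise KeyError(f"no HU entries for {level} keV (levels: {self.levels})")
        row = self.hu_table[level]
        lut = np.zeros(4, dtype=np.float32)
        for c in (BACKGROUND, WM, GM, CSF):
            lut[c] = row.get(c, 0.0)
        return lut


@dataclass(frozen=True)
class GridSpec:
    """Voxel grid: shape (axial slices along the third axis) and spacing in mm."""

    shape: tuple[int, int, int] = (64, 64, 32)
    spacing: tuple[float, float, float] = (3.0, 3.0, 4.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(n) != n or n < m for n, m in
                                       zip(self.shape, (16, 16, 8))):
            raise ValueError(f"grid shape must be at least (16, 16, 8), got {self.shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    def coordinates(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Physical voxel-centre coordinates (mm), origin at the grid centre."""
        axes = [(np.arange(n) - (n - 1) / 2.0) * s
                for n, s in zip(self.shape, self.spacing)]
        return np.meshgrid(*axes, indexing="ij")


def _ellipsoid_radius(x, y, z, semi_axes) -> np.ndarray:
    a, b, c = semi_axes
    return np.sqrt((x / a) ** 2 + (y / b) ** 2 + (z / c) ** 2)


def generate_label_volume(geometry: PhantomGeometry, grid: GridSpec,
                          seed: int) -> TissueLabelMap:
    """Voxelise one phantom into a tissue label volume.

    Outside-in the nesting is background, CSF shell, GM ribbon, WM core and
    a CSF-filled ventricle.  ``seed`` randomises the angular phase of the
    cortical folding, so equal geometries still differ between cases.

    Raises
    ------
    DegenerateGeometryError
        If any of the four classes ends up with zero voxels on this grid.
    """
    rng = np.random.default_rng(seed)
    phase_phi, phase_theta = rng.uniform(0.0, 2.0 * np.pi, size=2)
    x, y, z = grid.coordinates()

    labels = np.zeros(grid.shape, dtype=np.int16)
    labels[_ellipsoid_radius(x, y, z, geometry.head_semi_axes) <= 1.0] = CSF
    labels[_ellipsoid_radius(x, y, z, geometry.gm_semi_axes) <= 1.0] = GM

    # folded GM/WM interface: radial perturbation in spherical angle
    wm_axes = geometry.wm_semi_axes
    rho_wm = _ellipsoid_radius(x, y, z, wm_axes)
    r = np.sqrt(x * x + y * y + z * z)
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.arccos(np.clip(np.divide(z, r, out=np.zeros_like(r), where=r > 0),
                                  -1.0, 1.0))
    phi = np.arctan2(y, x)
    f = geometry.cortical_fold_frequency
    ripple = (geometry.cortical_fold_amplitude / np.mean(wm_axes)) * \
        np.sin(f * phi + phase_phi) * np.cos(f * theta + phase_theta)
    labels[rho_wm <= 1.0 + ripple] = WM

    labels[_ellipsoid_radius(x, y, z, geometry.ventricle_semi_axes) <= 1.0] = CSF

    counts = np.bincount(labels.ravel(), minlength=4)
    missing = [c for c in (BACKGROUND, WM, GM, CSF) if counts[c] == 0]
    if missing:
        raise DegenerateGeometryError(
            f"geometry collapses classes {missing} to zero voxels on grid {grid.shape}")
    return TissueLabelMap(labels, grid.spacing)


def render_spectral_stack(labels: TissueLabelMap, spectral: SpectralModel,
                          seed: int) -> SpectralStack:
    """Render a label volume into noisy HU volumes, one per keV level.

    Voxel value = table HU of its class + zero-mean Gaussian noise with the
    level's standard deviation; the noise fields are independent across
    levels and fully determined by ``seed``.
    """
    volumes = {}
    for level in spectral.levels:
        lut = spectral.hu_lookup(level)
        vol = lut[labels.data]
        sd = float(spectral.noise_sd[level])
        if sd > 0:
            rng = np.random.default_rng(np.random.SeedSequence([int(seed), int(level)]))
            vol = vol + rng.normal(0.0, sd, size=vol.shape)
        volumes[level] = vol.astype(np.float32)
    return SpectralStack(volumes, labels.spacing)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

@dataclass
class CohortManifest:
    """Index of a generated cohort: per-case file paths and seeds.

    Paths are stored relative to the manifest location so a cohort directory
    can be moved wholesale.
    """

    cases: list[dict]
    seed: int
    generator_version: str = _generator_version
    root: Path | None = None

    def __post_init__(self) -> None:
        ids = [c["id"] for c in self.cases]
        if len(set(ids)) != len(ids):
            raise ValueError("case ids must be unique")

    @property
    def case_ids(self) -> list[str]:
        return [c["id"] for c in self.cases]

    def _resolve(self, rel: str) -> Path:
        return (self.root / rel) if self.root is not None else Path(rel)

    def case_paths(self, case_id: str) -> dict:
        for c in self.cases:
            if c["id"] == case_id:
                return {
                    "labels": self._resolve(c["labels"]),
                    "vmi": {int(k): self._resolve(v) for k, v in c["vmi"].items()},
                }
        raise KeyError(f"no case {case_id!r} in manifest")

    def load_case(self, case_id: str) -> tuple[SpectralStack, TissueLabelMap]:
        paths = self.case_paths(case_id)
        volumes, spacing = {}, None
        for level, p in paths["vmi"].items():
            vol, spacing = read_volume(p)
            volumes[level] = vol
        lab, lab_spacing = read_volume(paths["labels"])
        labels = TissueLabelMap(np.rint(lab).astype(np.int16), lab_spacing)
        return SpectralStack(volumes, spacing), labels

    def load_all(self) -> dict[str, tuple[SpectralStack, TissueLabelMap]]:
        return {cid: self.load_case(cid) for cid in self.case_ids}

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "cases": self.cases,
            "seed": self.seed,
            "generator_version": self.generator_version,
        }
        path.write_text(json.dumps(payload, indent=2))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "CohortManifest":
        path = Path(path)
        payload = json.loads(path.read_text())
        manifest = cls(cases=payload["cases"], seed=payload["seed"],
                       generator_version=payload.get("generator_version", "unknown"),
                       root=path.parent)
        for cid in manifest.case_ids:
            for p in [manifest.case_paths(cid)["labels"],
                      *manifest.case_paths(cid)["vmi"].values()]:
                if not Path(p).exists():
                    raise FileNotFoundError(f"manifest references missing file {p}")
        return manifest


def case_seed(global_seed: int, index: int) -> int:
    """Deterministic per-case seed derived from the cohort seed."""
    ss = np.random.SeedSequence([int(global_seed), int(index)])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def generate_cohort(n_cases: int, out_dir: str | Path,
                    geometry: PhantomGeometry | None = None,
                    spectral: SpectralModel | None = None,
                    grid: GridSpec | None = None,
                    seed: int = 0) -> CohortManifest:
    """Generate ``n_cases`` phantom cases under ``out_dir`` and a manifest.

    Each case gets its own directory with three VMI volumes and one label
    volume (NIfTI); geometry is jittered per case from the per-case seed.
    """
    if n_cases < 1:
        raise ValueError(f"n_cases must be >= 1, got {n_cases}")
    geometry = geometry or PhantomGeometry()
    spectral = spectral or SpectralModel()
    grid = grid or GridSpec()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    cases = []
    for i in range(n_cases):
        cid = f"case_{i:03d}"
        cseed = case_seed(seed, i)
        rng = np.random.default_rng(cseed)
        geo = geometry.jittered(rng)
        labels = generate_label_volume(geo, grid, cseed)
        stack = render_spectral_stack(labels, spectral, cseed)
        cdir = out_dir / cid
        cdir.mkdir(exist_ok=True)
        record = {"id": cid, "seed": cseed, "vmi": {}, "labels": f"{cid}/labels.nii.gz"}
        write_volume(labels.data, labels.spacing, cdir / "labels.nii.gz")
        for level in stack.levels:
            rel = f"{cid}/vmi_{level:03d}.nii.gz"
            write_volume(stack[level], stack.spacing, out_dir / rel)
            record["vmi"][str(level)] = rel
        cases.append(record)

    manifest = CohortManifest(cases=cases, seed=int(seed), root=out_dir)
    manifest.save(out_dir / "manifest.json")
    return manifest
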