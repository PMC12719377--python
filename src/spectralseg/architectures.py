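"""Spectral U-Net family: U-Net / U-Net++ backbones with multi-energy input
variants.

Four variants share two backbones:

``baseline``
    Single-energy input (by default the 70 keV pseudo-3D triplet).
``aug``
    Architecturally identical to ``baseline``; the three energy levels are
    used as training-time augmentations, so only the sampling differs.
``fuse``
    One convolutional input pathway per energy level (50/70/120 keV); the
    pathway features are concatenated and fed to the backbone.
``gated``
    ``fuse`` plus an additive attention gate between the last up-convolution
    and the top skip connection (Oktay-style).

The default channel plans put the baseline U-Net at ~3.5 M and the baseline
U-Net++ at ~2.6 M trainable parameters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .nn import layers as L
from .nn import tensor as F
from .nn.tensor import Tensor

#: Default encoder channel plans (last entry is the bottleneck width).
UNET_WIDTHS: tuple[int, ...] = (24, 48, 96, 192, 288)
UNETPP_WIDTHS: tuple[int, ...] = (18, 36, 72, 144, 252)

BACKBONES = ("unet", "unetpp")
VARIANTS = ("baseline", "aug", "fuse", "gated")


@dataclass(frozen=True)
class ModelSpec:
    """Complete architectural description of one segmentation model.

    ``in_channels`` is derived: ``k_slices`` for single-energy variants
    (baseline/aug), ``3 * k_slices`` for the three-pathway variants
    (fuse/gated).
    """

    backbone: str = "unetpp"
    variant: str = "baseline"
    widths: tuple[int, ...] | None = None
    k_slices: int = 3
    n_classes: int = 4
    normalization: str = "instance"
    pathway_norm: str = "instance"
    activation: str | None = None
    attention_inter_channels: int | None = None

    def __post_init__(self) -> None:
        if self.backbone not in BACKBONES:
            raise ValueError(f"unknown backbone {self.backbone!r} (use one of {BACKBONES})")
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r} (use one of {VARIANTS})")
        if self.k_slices < 1 or self.k_slices % 2 == 0:
            raise ValueError(f"k_slices must be odd and positive, got {self.k_slices}")
        w = self.resolved_widths
        if len(w) < 3:
            raise ValueError(f"need encoder depth >= 3, got widths {w}")
        if any(c <= 0 for c in w):
            raise ValueError(f"channel widths must be positive, got {w}")
        if self.attention_inter_channels is not None and self.attention_inter_channels < 1:
            raise ValueError("attention_inter_channels must be >= 1")

    @property
    def resolved_widths(self) -> tuple[int, ...]:
        if self.widths is not None:
            return tuple(int(w) for w in self.widths)
        return UNET_WIDTHS if self.backbone == "unet" else UNETPP_WIDTHS

    @property
    def resolved_activation(self) -> str:
        if self.activation is not None:
            return self.activation
        return "prelu" if self.backbone == "unet" else "leaky_relu"

    @property
    def in_channels(self) -> int:
        return self.k_slices * (3 if self.variant in ("fuse", "gated") else 1)

    @property
    def depth(self) -> int:
        return len(self.resolved_widths)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["widths"] = list(self.resolved_widths)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        d = dict(d)
        if d.get("widths") is not None:
            d["widths"] = tuple(d["widths"])
        return cls(**d)


@dataclass(frozen=True)
class AttentionGateSpec:
    """Placement and width of the additive attention gate: it sits between
    the last up-convolution (gating signal) and the top skip connection."""

    inter_channels: int

    def __post_init__(self) -> None:
        if self.inter_channels < 1:
            raise ValueError("attention gate inter-channel width must be >= 1")


class FuseInputBlock(L.Module):
    """Three energy-specific input pathways, fused by concatenation.

    Each pathway is one convolution, an activation and a normalisation over
    its level's ``k``-slice triplet; outputs are concatenated channel-wise.
    """

    def __init__(self, k_slices: int, pathway_channels: int, *, activation: str,
                 normalization: str = "instance", rng: np.random.Generator,
                 dtype=np.float32) -> None:
        self.k_slices = k_slices
        self.pathway_channels = pathway_channels
        self.convs = [L.Conv2d(k_slices, pathway_channels, 3, rng=rng, dtype=dtype)
                      for _ in range(3)]
        self.acts = [L.make_activation(activation, dtype) for _ in range(3)]
        self.norms = [L.make_norm(normalization, pathway_channels) for _ in range(3)]

    @property
    def out_channels(self) -> int:
        return 3 * self.pathway_channels

    def forward_pathways(self, pathways: list[Tensor]) -> list[Tensor]:
        if len(pathways) != 3:
            raise ValueError(f"expected 3 pathways, got {len(pathways)}")
        shapes = {tuple(p.shape) for p in pathways}
        if len(shapes) != 1:
            raise ValueError(f"pathway shape mismatch: {sorted(shapes)}")
        return [n(a(c(p))) for p, c, a, n in
                zip(pathways, self.convs, self.acts, self.norms)]

    def forward(self, x: Tensor) -> Tensor:
        k = self.k_slices
        if x.shape[1] != 3 * k:
            raise ValueError(f"fuse input needs {3 * k} channels, got {x.shape[1]}")
        pathways = [F.channel_slice(x, i * k, (i + 1) * k) for i in range(3)]
        return F.concat(self.forward_pathways(pathways), axis=1)


class AttentionGate(L.Module):
    """Additive (Oktay-style) attention gate.

    Coefficients ``alpha = sigmoid(psi(relu(W_x x + W_g g)))`` scale the skip
    features position-wise; the gating signal is bilinearly resampled to the
    skip's spatial size when the two differ.
    """

    def __init__(self, skip_channels: int, gate_channels: int, inter_channels: int, *,
                 rng: np.random.Generator, dtype=np.float32) -> None:
        AttentionGateSpec(inter_channels)  # validate
        self.w_x = L.Conv2d(skip_channels, inter_channels, 1, rng=rng, dtype=dtype)
        self.w_g = L.Conv2d(gate_channels, inter_channels, 1, rng=rng, dtype=dtype)
        self.psi = L.Conv2d(inter_channels, 1, 1, rng=rng, dtype=dtype)
        self.skip_channels = skip_channels
        self.gate_channels = gate_channels

    def attention(self, skip: Tensor, gate: Tensor) -> Tensor:
        """Return the attention coefficient map ``alpha`` in (0, 1)."""
        if skip.shape[1] != self.skip_channels:
            raise ValueError(f"gate built for {self.skip_channels} skip channels, got {skip.shape[1]}")
        if gate.shape[1] != self.gate_channels:
            raise ValueError(f"gate built for {self.gate_channels} gate channels, got {gate.shape[1]}")
        gate = F.bilinear_resize(gate, skip.shape[2:])
        q = F.relu(self.w_x(skip) + self.w_g(gate))
        return F.sigmoid(self.psi(q))

    def forward(self, skip: Tensor, gate: Tensor, alpha_override: float | None = None) -> Tensor:
        if alpha_override is not None:
            alpha = Tensor(np.full((skip.shape[0], 1) + tuple(skip.shape[2:]),
                                   alpha_override, dtype=skip.dtype))
        else:
            alpha = self.attention(skip, gate)
        return F.mul(skip, alpha)


def _pad_to_multiple(x: Tensor, multiple: int) -> tuple[Tensor, int, int]:
    H, W = x.shape[2:]
    Hp = -(-H // multiple) * multiple
    Wp = -(-W // multiple) * multiple
    return F.reflect_pad2d(x, (0, Hp - H, 0, Wp - W)), H, W


class _SpectralNet(L.Module):
    """Shared plumbing for the two backbones (input handling, fuse, output)."""

    def __init__(self, spec: ModelSpec, rng: np.random.Generator, dtype) -> None:
        self.spec = spec
        self.dtype = dtype
        widths = spec.resolved_widths
        if spec.variant in ("fuse", "gated"):
            self.fuse = FuseInputBlock(
                spec.k_slices, widths[0], activation=spec.resolved_activation,
                normalization=spec.pathway_norm, rng=rng, dtype=dtype)
            self.stem_channels = self.fuse.out_channels
        else:
            self.fuse = None
            self.stem_channels = spec.in_channels

    def _prepare(self, x) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=self.dtype))
        if x.data.ndim != 4:
            raise ValueError(f"expected (batch, channels, H, W), got shape {x.shape}")
        if x.shape[1] != self.spec.in_channels:
            raise ValueError(
                f"{self.spec.backbone}/{self.spec.variant} expects "
                f"{self.spec.in_channels} input channels, got {x.shape[1]}")
        return x


class UNet(_SpectralNet):
    """Classic encoder-decoder U-Net with instance norm and PReLU defaults."""

    def __init__(self, spec: ModelSpec, *, rng: np.random.Generator, dtype=np.float32) -> None:
        super().__init__(spec, rng, dtype)
        w = spec.resolved_widths
        act, norm = spec.resolved_activation, spec.normalization
        D = len(w)
        self.pool = L.MaxPool2d()
        self.enc = []
        cin = self.stem_channels
        for f in w:
            self.enc.append(L.ConvBlock(cin, f, activation=act, normalization=norm,
                                        rng=rng, dtype=dtype))
            cin = f
        self.up = [L.ConvTranspose2d(w[i + 1], w[i], rng=rng, dtype=dtype)
                   for i in range(D - 1)]
        self.dec = [L.ConvBlock(2 * w[i], w[i], activation=act, normalization=norm,
                                rng=rng, dtype=dtype)
                    for i in range(D - 1)]
        self.head = L.Conv2d(w[0], spec.n_classes, 1, rng=rng, dtype=dtype)
        if spec.variant == "gated":
            inter = spec.attention_inter_channels or max(w[0] // 2, 1)
            self.gate = AttentionGate(w[0], w[0], inter, rng=rng, dtype=dtype)
        else:
            self.gate = None

    def forward(self, x, alpha_override: float | None = None) -> Tensor:
        x = self._prepare(x)
        D = len(self.spec.resolved_widths)
        x, H, W = _pad_to_multiple(x, 2 ** (D - 1))
        if self.fuse is not None:
            x = self.fuse(x)
        skips = []
        h = x
        for i, block in enumerate(self.enc):
            h = block(h)
            if i < D - 1:
                skips.append(h)
                h = self.pool(h)
        for i in range(D - 2, -1, -1):
            h = self.up[i](h)
            skip = skips[i]
            if i == 0 and self.gate is not None:
                skip = self.gate(skip, h, alpha_override=alpha_override)
            h = self.dec[i](F.concat([skip, h], axis=1))
        out = F.softmax_channels(self.head(h))
        return F.crop2d(out, H, W)


class UNetPlusPlus(_SpectralNet):
    """U-Net++ with dense nested skip connections (deep supervision off:
    the last nested node is the sole output)."""

    def __init__(self, spec: ModelSpec, *, rng: np.random.Generator, dtype=np.float32) -> None:
        super().__init__(spec, rng, dtype)
        w = spec.resolved_widths
        act, norm = spec.resolved_activation, spec.normalization
        D = len(w)
        self.pool = L.MaxPool2d()
        self.enc = []
        cin = self.stem_channels
        for f in w:
            self.enc.append(L.ConvBlock(cin, f, activation=act, normalization=norm,
                                        rng=rng, dtype=dtype))
            cin = f
        # nested nodes X[i][j] (j >= 1): up-convolution from level i+1 plus a
        # conv block over the concatenation of all earlier level-i nodes
        self.nested_up = []
        self.nested_block = []
        for i in range(D - 1):
            for j in range(1, D - i):
                self.nested_up.append(L.ConvTranspose2d(w[i + 1], w[i], rng=rng, dtype=dtype))
                self.nested_block.append(
                    L.ConvBlock((j + 1) * w[i], w[i], activation=act,
                                normalization=norm, rng=rng, dtype=dtype))
        self.head = L.Conv2d(w[0], spec.n_classes, 1, rng=rng, dtype=dtype)
        if spec.variant == "gated":
            inter = spec.attention_inter_channels or max(w[0] // 2, 1)
            self.gate = AttentionGate((D - 1) * w[0], w[0], inter, rng=rng, dtype=dtype)
        else:
            self.gate = None

    def _node_index(self, i: int, j: int) -> int:
        # layout order of (i, j>=1) pairs as built in __init__
        D = len(self.spec.resolved_widths)
        idx = 0
        for ii in range(i):
            idx += D - 1 - ii
        return idx + (j - 1)

    def forward(self, x, alpha_override: float | None = None) -> Tensor:
        x = self._prepare(x)
        D = len(self.spec.resolved_widths)
        x, H, W = _pad_to_multiple(x, 2 ** (D - 1))
        if self.fuse is not None:
            x = self.fuse(x)
        X: dict[tuple[int, int], Tensor] = {}
        h = x
        for i, block in enumerate(self.enc):
            h = block(h)
            X[(i, 0)] = h
            if i < D - 1:
                h = self.pool(h)
        for j in range(1, D):
            for i in range(D - j):
                k = self._node_index(i, j)
                up = self.nested_up[k](X[(i + 1, j - 1)])
                prev = [X[(i, jj)] for jj in range(j)]
                if i == 0 and j == D - 1 and self.gate is not None:
                    skip_bundle = F.concat(prev, axis=1) if len(prev) > 1 else prev[0]
                    skip_bundle = self.gate(skip_bundle, up, alpha_override=alpha_override)
                    X[(i, j)] = self.nested_block[k](F.concat([skip_bundle, up], axis=1))
                else:
                    X[(i, j)] = self.nested_block[k](F.concat(prev + [up], axis=1))
        out = F.softmax_channels(self.head(X[(0, D - 1)]))
        return F.crop2d(out, H, W)


SegmentationModel = UNet | UNetPlusPlus


def build_model(spec: ModelSpec, seed: int = 0, dtype=np.float32) -> SegmentationModel:
    """Instantiate the network described by ``spec`` with seeded He-normal
    initial weights."""
    rng = np.random.default_rng(seed)
    cls = UNet if spec.backbone == "unet" else UNetPlusPlus
    return cls(spec, rng=rng, dtype=dtype)


def count_parameters(model: L.Module) -> int:
    """Exact number of trainable scalars in ``model``."""
    return int(sum(p.data.size for p in model.parameters() if p.requires_grad))


def save_checkpoint(model: SegmentationModel, path: str | Path) -> None:
    """Serialise weights plus the embedded :class:`ModelSpec` (npz)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    state = model.state_dict()
    state["__modelspec__"] = np.frombuffer(
        json.dumps(model.spec.to_dict()).encode(), dtype=np.uint8)
    np.savez(path, **state)


def load_checkpoint(path: str | Path, dtype=np.float32) -> SegmentationModel:
    """Rebuild a model from a checkpoint written by :func:`save_checkpoint`."""
    path = Path(path)
    with np.load(path) as zf:
        state = {k: zf[k] for k in zf.files}
    raw = state.pop("__modelspec__")
    spec = ModelSpec.from_dict(json.loads(raw.tobytes().decode()))
    model = build_model(spec, seed=0, dtype=dtype)
    model.load_state_dict(state)
    return model
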