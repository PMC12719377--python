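"""Class-masked multi-class Dice loss.

Slice-wise training batches need not contain every tissue class; a plain
multi-class Dice loss then back-propagates from empty classes and drags
their predictions toward zero everywhere.  The masked loss computes the
Dice term per class and averages over the classes *present in the batch*
only, so absent classes contribute neither value nor gradient.
"""

from __future__ import annotations

import numpy as np

from .nn.tensor import Tensor, _make


def masked_dice_loss(pred, target, smooth: float = 1e-5) -> Tensor:
    """Mean Dice loss over the classes present in ``target``.

    Parameters
    ----------
    pred
        ``(B, C, H, W)`` class probabilities (each pixel sums to 1 over C);
        a :class:`~spectralseg.nn.Tensor` or an array.
    target
        One-hot ``(B, C, H, W)`` array (or tensor) of the same shape.
    smooth
        Symmetric smoothing term added to numerator and denominator.

    Returns
    -------
    Tensor
        Scalar loss ``mean_c [1 - (2 sum(p_c t_c) + s) / (sum p_c + sum t_c + s)]``
        over present classes ``c``.  Gradients with respect to absent-class
        predictions are exactly zero.
    """
    if not isinstance(pred, Tensor):
        pred = Tensor(np.asarray(pred))
    t = target.data if isinstance(target, Tensor) else np.asarray(target)
    if pred.shape != t.shape:
        raise ValueError(f"pred shape {pred.shape} != target shape {t.shape}")
    if pred.data.ndim != 4:
        raise ValueError(f"expected (batch, classes, H, W), got shape {pred.shape}")
    if smooth < 0:
        raise ValueError("smooth must be non-negative")

    axes = (0, 2, 3)
    t_sum = t.sum(axis=axes)
    present = t_sum > 0
    n_present = int(present.sum())
    if n_present == 0:
        raise ValueError("no class present in target batch; masked Dice loss undefined")

    p = pred.data
    inter = (p * t).sum(axis=axes)
    p_sum = p.sum(axis=axes)
    num = 2.0 * inter + smooth
    den = p_sum + t_sum + smooth
    # absent classes can hit 0/0 when smooth == 0; they are masked out below
    dice = np.divide(num, den, out=np.ones_like(den), where=den > 0)
    loss = float(np.mean(1.0 - dice[present]))

    def backward(g):
        if pred.requires_grad:
            # d/dp_c [1 - (2 S_pt + s)/(S_p + S_t + s)] = -(2 t - dice_c)/den_c
            scale = np.zeros_like(den)
            scale[present] = 1.0 / (n_present * den[present])
            gp = -(2.0 * t - dice[None, :, None, None]) * scale[None, :, None, None]
            pred._accumulate((float(g) * gp).astype(p.dtype))

    return _make(np.asarray(loss, dtype=p.dtype), (pred,), backward)
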