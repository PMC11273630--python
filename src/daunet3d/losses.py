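"""Tversky training objective on soft (probability-valued) predictions.

The Tversky index generalises Dice with asymmetric penalties on false
positives (weight ``alpha``) and false negatives (weight ``beta``):

    T = |P ∩ G| / (|P ∩ G| + alpha |P - G| + beta |G - P|)

evaluated with the standard soft relaxation |P ∩ G| = Σ p·g,
|P - G| = Σ p·(1-g), |G - P| = Σ (1-p)·g so the loss 1 - T is differentiable.
With alpha = beta = 0.5 the index reduces exactly to the soft Dice
coefficient.  Defaults alpha = 0.7, beta = 0.3 weight false positives more
heavily, the usual choice for organ segmentation where over-segmentation
into neighbouring tissue is the dominant failure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor
from .volume_io import SegmentationMask


@dataclass(frozen=True)
class TverskyParams:
    alpha: float = 0.7
    beta: float = 0.3
    smooth: float = 1e-6

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be >= 0")
        if self.smooth <= 0:
            raise ValueError("smooth must be > 0")


def _coerce(pred, gt) -> tuple[Tensor, np.ndarray]:
    p = nn.as_tensor(pred)
    g = gt.voxels if isinstance(gt, SegmentationMask) else np.asarray(gt)
    g = g.astype(p.data.dtype)  # match precision of the prediction
    if p.shape != g.shape:
        if p.ndim == g.ndim + 1 and p.shape[0] == 1:  # drop channel axis
            g = g[None]
        else:
            raise ValueError(f"shape mismatch: pred {p.shape} vs gt {g.shape}")
    if p.data.min() < -1e-6 or p.data.max() > 1 + 1e-6:
        raise ValueError("predictions must be probabilities in [0, 1]")
    return p, g


def tversky_index(pred, gt, params: TverskyParams = TverskyParams()) -> Tensor:
    """Soft Tversky index in [0, 1]; 1 means perfect agreement.

    Accepts a probability map (Tensor or array) and a mask (SegmentationMask
    or array).  The smooth term defines the both-empty case as T = 1.
    """
    p, g = _coerce(pred, gt)
    inter = (p * g).sum()
    fp = (p * (1.0 - g)).sum()
    fn = ((1.0 - p) * g).sum()
    # constants at the prediction's precision (float64 inputs stay exact)
    dt = p.data.dtype
    alpha = np.asarray(params.alpha, dtype=dt)
    beta = np.asarray(params.beta, dtype=dt)
    s = np.asarray(params.smooth, dtype=dt)
    return (inter + s) / (inter + fp * alpha + fn * beta + s)


def tversky_loss(pred, gt, params: TverskyParams = TverskyParams()) -> Tensor:
    """1 - Tversky index; the training objective."""
    return 1.0 - tversky_index(pred, gt, params)


def soft_dice(pred, gt, smooth: float = 1e-6) -> Tensor:
    """Soft Dice coefficient 2Σpg / (Σp + Σg); equals Tversky at α = β = 0.5."""
    p, g = _coerce(pred, gt)
    inter = (p * g).sum()
    total = p.sum() + nn.as_tensor(g).sum()
    s = np.asarray(smooth, dtype=p.data.dtype)
    return (2.0 * inter + s) / (total + s)
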