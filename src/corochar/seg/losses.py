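"""Weighted Dice + Focal loss (DFL).

For per-voxel foreground posteriors yhat and binary targets y::

    DFL = lambda_F * mean_i[ -alpha (1-yhat_i)^gamma y_i log(yhat_i)
                             - (1-alpha) yhat_i^gamma (1-y_i) log(1-yhat_i) ]
        + lambda_D * [ 1 - 2 sum(y yhat) / (sum(y) + sum(yhat)) ]

The focal term counters the extreme foreground/background imbalance of
vascular segmentation (alpha shifts weight onto the foreground class, gamma
down-weights easy voxels); the Dice term optimizes overlap directly.  The
focal sum is aggregated as a mean over voxels so the loss scale is
independent of patch size.  Posteriors are clamped to [1e-7, 1 - 1e-7] to
keep the logarithms finite.

Stage defaults: alpha = 0.6, gamma = 2; stage-1 weights lambda_F = 1.1,
lambda_D = 0.4; stage-2 weights lambda_F = 0.5, lambda_D = 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["LossParams", "dice_focal_loss", "dice_focal_grad"]

_CLAMP = 1e-7


@dataclass
class LossParams:
    alpha: float = 0.6
    gamma: float = 2.0
    lambda_focal: float = 1.1
    lambda_dice: float = 0.4

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.gamma < 0 or self.lambda_focal < 0 or self.lambda_dice < 0:
            raise ValueError("gamma and stage weights must be non-negative")

    @classmethod
    def stage1(cls) -> "LossParams":
        return cls(alpha=0.6, gamma=2.0, lambda_focal=1.1, lambda_dice=0.4)

    @classmethod
    def stage2(cls) -> "LossParams":
        return cls(alpha=0.6, gamma=2.0, lambda_focal=0.5, lambda_dice=1.0)


def _prepare(y_hat: np.ndarray, y: np.ndarray):
    y_hat = np.asarray(y_hat, dtype=float)
    y = np.asarray(y, dtype=float)
    if y_hat.shape != y.shape:
        raise ValueError(f"shape mismatch {y_hat.shape} vs {y.shape}")
    return np.clip(y_hat, _CLAMP, 1.0 - _CLAMP), y


def dice_focal_loss(y_hat: np.ndarray, y: np.ndarray,
                    params: LossParams | None = None) -> float:
    params = params or LossParams()
    p, y = _prepare(y_hat, y)
    a, g = params.alpha, params.gamma
    focal = (-a * (1 - p) ** g * y * np.log(p)
             - (1 - a) * p**g * (1 - y) * np.log(1 - p)).mean()
    denom = y.sum() + p.sum()
    dice = 1.0 - (2.0 * (y * p).sum() / denom if denom > 0 else 1.0)
    return float(params.lambda_focal * focal + params.lambda_dice * dice)


def dice_focal_grad(y_hat: np.ndarray, y: np.ndarray,
                    params: LossParams | None = None) -> np.ndarray:
    """Analytic d(DFL)/d(yhat), same shape as the inputs."""
    params = params or LossParams()
    p, y = _prepare(y_hat, y)
    a, g = params.alpha, params.gamma
    n = p.size
    d_focal = (-a * y * ((1 - p) ** g / p - g * (1 - p) ** (g - 1) * np.log(p))
               - (1 - a) * (1 - y) * (g * p ** (g - 1) * np.log(1 - p)
                                      - p**g / (1 - p))) / n
    denom = y.sum() + p.sum()
    if denom > 0:
        inter = (y * p).sum()
        d_dice = -2.0 * (y * denom - inter) / denom**2
    else:
        d_dice = np.zeros_like(p)
    return params.lambda_focal * d_focal + params.lambda_dice * d_dice
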