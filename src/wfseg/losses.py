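"""Combined binary cross-entropy + soft Dice objective.

Both terms act on the three overlapping region channels (WT, TC, ET) of
the sigmoid output: BCE is the voxelwise −(u log v + (1−u) log(1−v))
averaged over voxels and regions, and the Dice term is 1 − (2Σuv + ε) /
(Σu + Σv + ε) per region, averaged.  The total objective is their sum.
ε keeps the Dice ratio defined when a region is absent from both target
and prediction (the empty-empty case scores a loss of 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class LossConfig:
    epsilon: float = 1e-5  # Dice smoothing
    clip: float = 1e-7  # floor for the BCE logarithms
    region_weights: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if any(w < 0 for w in self.region_weights) or sum(self.region_weights) == 0:
            raise ValueError("region_weights must be nonnegative with positive sum")


def _as_regions(u: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    if u.shape != v.shape:
        raise ValueError(f"target shape {u.shape} != prediction shape {v.shape}")
    if u.ndim == 3:  # single region
        u, v = u[None], v[None]
    return u, v


def _weights(n_regions: int, config: LossConfig) -> np.ndarray:
    if n_regions == len(config.region_weights):
        w = np.asarray(config.region_weights, dtype=np.float64)
    else:
        w = np.ones(n_regions)
    return w / w.sum()


def bce_loss(u: np.ndarray, v: np.ndarray, config: LossConfig | None = None) -> float:
    """Region-weighted mean binary cross-entropy over voxels."""
    config = config or LossConfig()
    u, v = _as_regions(u, v)
    v = np.clip(v, config.clip, 1.0 - config.clip)
    per_region = -(u * np.log(v) + (1 - u) * np.log(1 - v)).mean(axis=(1, 2, 3))
    return float(per_region @ _weights(u.shape[0], config))


def dice_loss(u: np.ndarray, v: np.ndarray, config: LossConfig | None = None) -> float:
    """Region-weighted mean soft Dice loss, in [0, 1]."""
    config = config or LossConfig()
    u, v = _as_regions(u, v)
    eps = config.epsilon
    inter = (u * v).sum(axis=(1, 2, 3))
    sizes = u.sum(axis=(1, 2, 3)) + v.sum(axis=(1, 2, 3))
    per_region = 1.0 - (2.0 * inter + eps) / (sizes + eps)
    return float(per_region @ _weights(u.shape[0], config))


def total_loss(u: np.ndarray, v: np.ndarray, config: LossConfig | None = None) -> float:
    """BCE + Dice."""
    config = config or LossConfig()
    return bce_loss(u, v, config) + dice_loss(u, v, config)


def soft_dice(u: np.ndarray, v: np.ndarray, epsilon: float = 1e-5) -> float:
    """Soft Dice coefficient (not the loss) for one region pair."""
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    return float((2.0 * (u * v).sum() + epsilon) / (u.sum() + v.sum() + epsilon))
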