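"""Task losses and the Gaussian fovea target map.

Three losses drive the four tasks: pixel-averaged binary cross-entropy
for the disc and cup maps, an L1 loss summed over pixels for the fovea
saliency map (the target values are continuous, not binary), and a focal
loss for the glaucoma label, whose modulating factor (1 - p_t)^gamma
down-weights confidently classified samples so that the ~10% positive
class is not drowned out.  All are pure deterministic functions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

EPS = 1e-7  # probability clamp for all logarithms


def _clamp(p: np.ndarray) -> np.ndarray:
    return np.clip(p, EPS, 1.0 - EPS)


def bce_loss(pred: np.ndarray, target: np.ndarray) -> float:
    """Binary cross-entropy in nats, averaged over every pixel.

    ``pred`` holds probabilities in [0, 1]; ``target`` is binary.
    """
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    if pred.min() < 0 or pred.max() > 1:
        raise ValueError("pred must lie in [0, 1]")
    if not np.all((target == 0) | (target == 1)):
        raise ValueError("target must be binary")
    p = _clamp(pred)
    return float(-np.mean(target * np.log(p) + (1 - target) * np.log(1 - p)))


def l1_loss(pred: np.ndarray, target: np.ndarray) -> float:
    """Sum (not mean) of absolute deviations between two real maps."""
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    return float(np.abs(target - pred).sum())


def focal_loss(prob, label, gamma: float = 2.0) -> float:
    """Focal loss -(1 - p_t)^gamma * log(p_t) in nats, gamma >= 0.

    Accepts scalars or equally-shaped arrays (averaged over elements).
    Reduces to binary cross-entropy at gamma = 0.
    """
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    prob = np.asarray(prob, dtype=np.float64)
    label = np.asarray(label, dtype=np.float64)
    if not np.all((label == 0) | (label == 1)):
        raise ValueError("label must be 0 or 1")
    p = _clamp(prob)
    p_t = np.where(label == 1, p, 1 - p)
    return float(np.mean(-((1 - p_t) ** gamma) * np.log(p_t)))


@dataclass(frozen=True)
class SaliencyMapSpec:
    """Isotropic Gaussian bump encoding a landmark position.

    ``center_x``/``center_y`` are 0-based pixel coordinates (column/row,
    fractional allowed), ``sigma`` the common spread in pixels (equal
    variances, zero covariance).  The map is peak-normalized to 1.
    """

    center_x: float
    center_y: float
    sigma: float
    height: int
    width: int

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if not (0 <= self.center_x <= self.width - 1 and 0 <= self.center_y <= self.height - 1):
            raise ValueError(
                f"center ({self.center_x}, {self.center_y}) outside a {self.height}x{self.width} map"
            )


def make_fovea_map(spec: SaliencyMapSpec) -> np.ndarray:
    """Render the Gaussian target map described by ``spec``.

    Value at pixel (r, c) is exp(-((c-cx)^2 + (r-cy)^2) / (2 sigma^2)),
    rescaled so the maximum (attained at the grid point nearest the
    center) is exactly 1.
    """
    r = np.arange(spec.height, dtype=np.float64)[:, None]
    c = np.arange(spec.width, dtype=np.float64)[None, :]
    d2 = (c - spec.center_x) ** 2 + (r - spec.center_y) ** 2
    m = np.exp(-d2 / (2.0 * spec.sigma**2))
    return m / m.max()


def default_sigma(input_size: int) -> float:
    """Default saliency spread: 8 px at 512-px input, scaled linearly."""
    return input_size * 8.0 / 512.0
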