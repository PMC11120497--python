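"""Region-restricted segmentation losses and the fused training objective.

The base loss L_seg is a convex combination of soft-Dice and binary
cross-entropy. The copy-paste objective evaluates it separately on the
labeled-origin and unlabeled-origin regions of each synthetic image:

    L_in  = L_seg(Q_in,  Y_in,  M)       + alpha * L_seg(Q_in,  Y_in,  1-M)
    L_out = L_seg(Q_out, Y_out, 1-M)     + alpha * L_seg(Q_out, Y_out, M)

and the total fuses in the direct supervised loss on the raw labeled
images with weight gamma:

    L = L_in + L_out + gamma * (L_i + L_j)

Restricting L_seg to a region means: the cross-entropy is averaged over
in-region pixels only, and every sum in the Dice term runs over the region
only. With the all-ones region this is exactly the plain full-image loss,
and gamma = 0 recovers the pure copy-paste objective.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

#: floor used when clamping probabilities inside log()
CLAMP = 1e-7


@dataclass(frozen=True)
class LossConfig:
    """Weights and constants of the training objective.

    alpha   weight of the unlabeled-origin region inside each synthetic
            image (the labeled-origin region always has weight 1)
    gamma   weight of the direct supervised loss on raw labeled images;
            0 disables the fusion entirely
    dice_weight / ce_weight
            convex mixture of the Dice and cross-entropy terms of L_seg
    epsilon Dice smoothing constant
    """

    alpha: float = 0.5
    gamma: float = 0.5
    dice_weight: float = 0.5
    ce_weight: float = 0.5
    epsilon: float = 1e-5

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.gamma < 0:
            raise ValueError("alpha and gamma must be non-negative")
        if abs(self.dice_weight + self.ce_weight - 1.0) > 1e-9:
            raise ValueError("dice_weight + ce_weight must equal 1")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


@dataclass
class LossBundle:
    """Scalar loss components of one training step."""

    l_in: float
    l_out: float
    l_i: float
    l_j: float
    total: float

    def as_dict(self) -> dict[str, float]:
        return {"l_in": self.l_in, "l_out": self.l_out,
                "l_i": self.l_i, "l_j": self.l_j, "total": self.total}


def _validate(q: np.ndarray, y: np.ndarray, region: np.ndarray | None):
    q = np.asarray(q, dtype=np.float64)
    y = np.asarray(y)
    if q.shape != y.shape:
        raise ValueError(f"shape mismatch: Q {q.shape} vs Y {y.shape}")
    if q.min() < 0 or q.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("ground truth must be binary")
    if region is None:
        region = np.ones_like(y, dtype=np.uint8)
    else:
        region = np.asarray(region)
        if region.shape != q.shape:
            raise ValueError(
                f"region shape {region.shape} does not match {q.shape}")
        if not np.isin(region, (0, 1)).all():
            raise ValueError("region mask must be binary")
    return q, y.astype(np.float64), region.astype(bool)


def seg_loss(q: np.ndarray, y: np.ndarray,
             region: np.ndarray | None = None,
             cfg: LossConfig | None = None) -> float:
    """Dice + cross-entropy of a foreground-probability map against a
    binary target, restricted to ``region`` (all pixels when None).

    An all-zero region supervises nothing and scores 0 (with a warning).
    """
    cfg = cfg or LossConfig()
    q, y, reg = _validate(q, y, region)
    n = int(reg.sum())
    if n == 0:
        logger.warning("seg_loss: empty supervision region, returning 0")
        return 0.0
    qr, yr = q[reg], y[reg]
    qc = np.clip(qr, CLAMP, 1.0 - CLAMP)
    ce = -np.mean(yr * np.log(qc) + (1.0 - yr) * np.log(1.0 - qc))
    inter = float((qr * yr).sum())
    denom = float(qr.sum() + yr.sum())
    dice = 1.0 - (2.0 * inter + cfg.epsilon) / (denom + cfg.epsilon)
    return float(cfg.dice_weight * dice + cfg.ce_weight * ce)


def seg_loss_grad(q: np.ndarray, y: np.ndarray,
                  region: np.ndarray | None = None,
                  cfg: LossConfig | None = None
                  ) -> tuple[float, np.ndarray]:
    """``seg_loss`` plus its analytic gradient with respect to Q.

    Used by the trainer; the gradient is zero outside the region and at
    pixels where the clamp is active in the cross-entropy term.
    """
    cfg = cfg or LossConfig()
    q, y, reg = _validate(q, y, region)
    grad = np.zeros_like(q)
    n = int(reg.sum())
    if n == 0:
        logger.warning("seg_loss_grad: empty supervision region")
        return 0.0, grad
    qr, yr = q[reg], y[reg]
    qc = np.clip(qr, CLAMP, 1.0 - CLAMP)
    ce = -np.mean(yr * np.log(qc) + (1.0 - yr) * np.log(1.0 - qc))
    unclamped = (qr > CLAMP) & (qr < 1.0 - CLAMP)
    dce = -(yr / qc - (1.0 - yr) / (1.0 - qc)) / n
    dce[~unclamped] = 0.0
    inter = float((qr * yr).sum())
    denom = float(qr.sum() + yr.sum())
    dice = 1.0 - (2.0 * inter + cfg.epsilon) / (denom + cfg.epsilon)
    # d/dq of -(2*inter+eps)/(denom+eps)
    ddice = (-2.0 * yr * (denom + cfg.epsilon)
             + (2.0 * inter + cfg.epsilon)) / (denom + cfg.epsilon) ** 2
    grad[reg] = cfg.dice_weight * ddice + cfg.ce_weight * dce
    loss = float(cfg.dice_weight * dice + cfg.ce_weight * ce)
    return loss, grad


def masked_pair_losses(q_in: np.ndarray, q_out: np.ndarray,
                       y_in: np.ndarray, y_out: np.ndarray,
                       mask: np.ndarray,
                       cfg: LossConfig | None = None
                       ) -> tuple[float, float]:
    """Synthetic-image losses of one copy-paste pair.

    The labeled-origin region (mask for X_in, its complement for X_out)
    contributes at weight 1; the unlabeled-origin region at weight alpha.
    """
    cfg = cfg or LossConfig()
    inv = (1 - np.asarray(mask)).astype(np.uint8)
    l_in = (seg_loss(q_in, y_in, mask, cfg)
            + cfg.alpha * seg_loss(q_in, y_in, inv, cfg))
    l_out = (seg_loss(q_out, y_out, inv, cfg)
             + cfg.alpha * seg_loss(q_out, y_out, mask, cfg))
    return l_in, l_out


def total_loss(l_in: float, l_out: float, l_i: float, l_j: float,
               cfg: LossConfig | None = None) -> LossBundle:
    """Fused objective L = L_in + L_out + gamma * (L_i + L_j)."""
    cfg = cfg or LossConfig()
    parts = (l_in, l_out, l_i, l_j)
    if not all(np.isfinite(parts)):
        raise FloatingPointError(
            f"non-finite loss component: in={l_in} out={l_out} "
            f"i={l_i} j={l_j} (training diverged?)")
    total = l_in + l_out + cfg.gamma * (l_i + l_j)
    return LossBundle(float(l_in), float(l_out), float(l_i), float(l_j),
                      float(total))
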