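"""Bidirectional copy-paste (BCP) synthesis between labeled and unlabeled
images.

A rectangular binary mask M marks the region copied from the "foreground"
image. For a labeled pair (i, j) and an unlabeled pair (p, q):

    X_in  = X_j^l  * M + X_p^u * (1 - M)   (labeled patch on unlabeled bg)
    X_out = X_q^u  * M + X_i^l * (1 - M)   (unlabeled patch on labeled bg)

The supervisory targets mix real ground truth with teacher pseudo-labels
under the same mask:

    Y_in  = Y_j^l  * M + pseudo(X_p^u) * (1 - M)
    Y_out = pseudo(X_q^u) * M + Y_i^l  * (1 - M)

where ``pseudo`` thresholds the teacher's foreground probability at 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import UNet, WeightSet, forward


class BatchCompositionError(ValueError):
    """Raised when there are too few images to form copy-paste pairs."""


@dataclass
class SyntheticBatch:
    """One bidirectional copy-paste pair with its provenance indices."""

    x_in: np.ndarray
    x_out: np.ndarray
    y_in: np.ndarray
    y_out: np.ndarray
    mask: np.ndarray
    i: int
    j: int
    p: int
    q: int

    def __post_init__(self) -> None:
        if self.i == self.j or self.p == self.q:
            raise BatchCompositionError(
                "copy-paste pairs need distinct images (i != j, p != q)")
        shape = self.mask.shape
        for arr in (self.x_in, self.x_out, self.y_in, self.y_out):
            if arr.shape[:2] != shape:
                raise ValueError("all arrays in a pair must share H x W")


def _check_binary(m: np.ndarray, name: str = "mask") -> None:
    if not np.isin(m, (0, 1)).all():
        raise ValueError(f"{name} must contain only 0 and 1")


def generate_mask(h: int, w: int, ratio: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Rectangular copy region: ``floor(ratio*h) x floor(ratio*w)`` ones at
    a uniformly random position, zeros elsewhere.

    ``ratio`` scales each spatial dimension (the default 2/3 marks 4/9 of
    the pixels for copying).
    """
    if not 0.0 < ratio <= 1.0:
        raise ValueError(f"mask ratio must be in (0, 1], got {ratio}")
    rh, rw = int(ratio * h), int(ratio * w)
    if rh < 1 or rw < 1:
        raise ValueError(f"mask {ratio} too small for image {h}x{w}")
    r0 = int(rng.integers(0, h - rh + 1))
    c0 = int(rng.integers(0, w - rw + 1))
    m = np.zeros((h, w), dtype=np.uint8)
    m[r0:r0 + rh, c0:c0 + rw] = 1
    return m


def copy_paste(fg: np.ndarray, bg: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Selector composition: ``fg`` where mask is 1, ``bg`` where it is 0.

    Exact (bit-identical) per pixel and channel; images may be (H, W) or
    (H, W, C).
    """
    if fg.shape != bg.shape:
        raise ValueError(f"image shapes differ: {fg.shape} vs {bg.shape}")
    if mask.shape != fg.shape[:2]:
        raise ValueError(
            f"mask shape {mask.shape} does not match image {fg.shape}")
    _check_binary(mask)
    sel = mask.astype(bool)
    if fg.ndim == 3:
        sel = sel[..., None]
    return np.where(sel, fg, bg)


def binarize(prob: np.ndarray) -> np.ndarray:
    """Pseudo-label: 1 where the foreground probability strictly exceeds
    0.5, else 0 (so an exactly-0.5 pixel is background)."""
    prob = np.asarray(prob)
    if prob.min() < 0 or prob.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    return (prob > 0.5).astype(np.uint8)


def synthesize_gt(y_fg: np.ndarray, y_bg: np.ndarray,
                  mask: np.ndarray) -> np.ndarray:
    """Compose a synthetic ground truth with the same selector as the
    images: ``y_fg`` inside the mask, ``y_bg`` outside."""
    _check_binary(y_fg, "y_fg")
    _check_binary(y_bg, "y_bg")
    out = copy_paste(y_fg.astype(np.uint8), y_bg.astype(np.uint8), mask)
    return out.astype(np.uint8)


def make_synthetic_batch(labeled: list[tuple[np.ndarray, np.ndarray]],
                         unlabeled: list[np.ndarray],
                         teacher: WeightSet,
                         ratio: float,
                         rng: np.random.Generator,
                         model: UNet | None = None) -> list[SyntheticBatch]:
    """Build one batch of bidirectional copy-paste pairs.

    The labeled and unlabeled half-batches are each shuffled and split into
    two halves (first half supplies i / p, second half j / q), which
    guarantees i != j and p != q while using every image once. One mask M
    is shared by the X_in and X_out of a pair. Teacher inference runs in
    evaluation mode and its output is used only as data (no gradients flow
    through pseudo-labels).
    """
    if len(labeled) < 2 or len(unlabeled) < 2:
        raise BatchCompositionError(
            "need at least 2 labeled and 2 unlabeled images to form pairs")
    lab_idx = rng.permutation(len(labeled))
    unl_idx = rng.permutation(len(unlabeled))
    n_pairs = min(len(labeled), len(unlabeled)) // 2
    i_idx, j_idx = lab_idx[:n_pairs], lab_idx[n_pairs:2 * n_pairs]
    p_idx, q_idx = unl_idx[:n_pairs], unl_idx[n_pairs:2 * n_pairs]

    xu = np.stack([unlabeled[k] for k in np.concatenate([p_idx, q_idx])])
    probs = forward(xu, teacher, model=model)
    pseudo = binarize(probs)
    pseudo_p, pseudo_q = pseudo[:n_pairs], pseudo[n_pairs:]

    h, w = labeled[0][0].shape[:2]
    batches = []
    for k in range(n_pairs):
        i, j = int(i_idx[k]), int(j_idx[k])
        p, q = int(p_idx[k]), int(q_idx[k])
        x_i, y_i = labeled[i]
        x_j, y_j = labeled[j]
        m = generate_mask(h, w, ratio, rng)
        batches.append(SyntheticBatch(
            x_in=copy_paste(x_j, unlabeled[p], m),
            x_out=copy_paste(unlabeled[q], x_i, m),
            y_in=synthesize_gt(y_j, pseudo_p[k], m),
            y_out=synthesize_gt(pseudo_q[k], y_i, m),
            mask=m, i=i, j=j, p=p, q=q))
    return batches
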