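"""Two-stage training: supervised pre-training of Θp on labeled images,
then semi-supervised training of the student Θs with an EMA teacher Θt.

Stage 1 (``pretrain``) is ordinary supervised learning on the labeled
subset only; the best-validation-Dice checkpoint becomes Θp. Stage 2
(``ssl_train``) initialises both teacher and student from Θp, and per
iteration: composes bidirectional copy-paste batches with teacher
pseudo-labels, takes one SGD step on the student under the fused loss

    L = L_in + L_out + gamma * (L_i + L_j),

then tracks the teacher as an exponential moving average of the student,

    Θt <- lambda * Θt + (1 - lambda) * Θs,

including batch-norm running statistics. The optimiser never touches Θt.
All randomness (batch sampling, mask placement, weight init) flows from a
single seed through independent child streams, so runs are reproducible
bit-for-bit on one machine.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .bcp import copy_paste, generate_mask, make_synthetic_batch, synthesize_gt
from .evaluation import dice_score, jaccard_index
from .losses import LossConfig, seg_loss_grad, total_loss
from .model import (
    ModelConfig,
    UNet,
    WeightSet,
    save_checkpoint,
    softmax_foreground,
)


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation hyperparameters.

    Defaults follow the reference setting (SGD lr 0.01, momentum 0.9,
    weight decay 1e-4, half-batches of 12, lambda 0.99, mask ratio 2/3)
    except for the iteration counts, whose desk-scale defaults of 300
    replace the full-scale 10k/30k; full scale is reachable via config.
    """

    learning_rate: float = 0.01
    momentum: float = 0.9
    weight_decay: float = 1e-4
    batch_labeled: int = 12
    batch_unlabeled: int = 12
    pretrain_iterations: int = 300
    ssl_iterations: int = 300
    ema_lambda: float = 0.99
    mask_ratio: float = 2.0 / 3.0
    label_ratio: float = 0.05
    eval_every: int = 50
    poly_lr_decay: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.ema_lambda <= 1.0:
            raise ValueError("ema_lambda must lie in [0, 1]")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be non-negative")
        if self.batch_labeled % 2 or self.batch_unlabeled % 2:
            raise ValueError("batch sizes must be even (images are paired)")
        if not 0.0 < self.mask_ratio <= 1.0:
            raise ValueError("mask_ratio must be in (0, 1]")


class _SGD:
    """SGD with momentum and decoupled-from-nothing L2 weight decay
    (gradient += wd * param, the classic convention)."""

    def __init__(self, cfg: TrainConfig) -> None:
        self.cfg = cfg
        self.velocity: dict[str, np.ndarray] = {}

    def step(self, model: UNet, lr: float) -> None:
        for name, param, grad in model.parameters():
            g = grad + self.cfg.weight_decay * param
            v = self.velocity.get(name)
            if v is None:
                v = np.zeros_like(param)
                self.velocity[name] = v
            v *= self.cfg.momentum
            v += g
            param -= lr * v


def _streams(seed: int) -> dict[str, np.random.Generator]:
    data, mask, init = np.random.SeedSequence(seed).spawn(3)
    return {"data": np.random.default_rng(data),
            "mask": np.random.default_rng(mask),
            "init": np.random.default_rng(init)}


def _lr_at(cfg: TrainConfig, it: int, total: int) -> float:
    if not cfg.poly_lr_decay:
        return cfg.learning_rate
    return cfg.learning_rate * (1.0 - it / max(total, 1)) ** 0.9


def _sample_indices(rng: np.random.Generator, n: int,
                    size: int) -> np.ndarray:
    """Without replacement when possible; tiny pools are resampled."""
    return rng.choice(n, size=size, replace=n < size)


class _Logger:
    def __init__(self, path: str | Path | None) -> None:
        self.fh = open(path, "w") if path is not None else None

    def write(self, record: dict) -> None:
        if self.fh is not None:
            self.fh.write(json.dumps(record) + "\n")
            self.fh.flush()

    def close(self) -> None:
        if self.fh is not None:
            self.fh.close()


def _probability_grad_to_logits(p: np.ndarray,
                                dp: np.ndarray) -> np.ndarray:
    """Chain d(loss)/d(foreground prob) through the two-class softmax."""
    g = dp * p * (1.0 - p)
    return np.stack([-g, g], axis=-1).astype(np.float32)


def ema_update(theta_t: WeightSet, theta_s: WeightSet,
               lam: float) -> WeightSet:
    """In-place exponential moving average of every array in the teacher,
    batch-norm running statistics included."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must lie in [0, 1]")
    for group_t, group_s in ((theta_t.params, theta_s.params),
                             (theta_t.buffers, theta_s.buffers)):
        if group_t.keys() != group_s.keys():
            raise ValueError("teacher/student weight sets do not match")
        for key, arr_t in group_t.items():
            arr_s = group_s[key]
            if arr_t.shape != arr_s.shape:
                raise ValueError(f"shape mismatch for {key}")
            arr_t *= lam
            arr_t += (1.0 - lam) * arr_s
    return theta_t


def evaluate_checkpoint(ws: WeightSet,
                        val: list[tuple[np.ndarray, np.ndarray]],
                        model: UNet | None = None,
                        batch_size: int = 25) -> tuple[float, float]:
    """Mean per-image Dice and Jaccard of thresholded predictions."""
    if not val:
        raise ValueError("validation set is empty")
    if model is None:
        model = UNet(ws.config, seed=0)
    model.load_state(ws)
    dices, jaccards = [], []
    for start in range(0, len(val), batch_size):
        chunk = val[start:start + batch_size]
        x = np.stack([img for img, _ in chunk]).astype(np.float32)
        probs = softmax_foreground(model.forward_logits(x, train=False))
        preds = (probs > 0.5).astype(np.uint8)
        for pred, (_, gt) in zip(preds, chunk):
            dices.append(dice_score(pred, gt))
            jaccards.append(jaccard_index(pred, gt))
    return float(np.mean(dices)), float(np.mean(jaccards))


def _supervised_step(model: UNet, sgd: _SGD, xs: np.ndarray,
                     ys: list[np.ndarray], loss_cfg: LossConfig,
                     lr: float) -> float:
    """One SGD step on the plain full-image loss of a labeled batch."""
    logits = model.forward_logits(xs, train=True)
    p = softmax_foreground(logits)
    n = len(ys)
    dp = np.zeros_like(p)
    loss_sum = 0.0
    for k in range(n):
        lk, gk = seg_loss_grad(p[k], ys[k], None, loss_cfg)
        loss_sum += lk
        dp[k] = gk / n
    model.zero_grad()
    model.backward(_probability_grad_to_logits(p, dp))
    sgd.step(model, lr)
    return loss_sum / n


def _synthetic_pretrain_step(model: UNet, sgd: _SGD,
                             batch: list[tuple[np.ndarray, np.ndarray]],
                             mask_rng: np.random.Generator,
                             cfg: TrainConfig, loss_cfg: LossConfig,
                             lr: float) -> float:
    """One step of copy-paste pre-training among labeled images only
    (both regions carry real ground truth; no teacher involved)."""
    n_pairs = len(batch) // 2
    xs, ys, masks = [], [], []
    for k in range(n_pairs):
        (x_i, y_i), (x_j, y_j) = batch[k], batch[n_pairs + k]
        m = generate_mask(x_i.shape[0], x_i.shape[1], cfg.mask_ratio,
                          mask_rng)
        xs.append(copy_paste(x_j, x_i, m))
        ys.append(synthesize_gt(y_j, y_i, m))
        xs.append(copy_paste(x_i, x_j, m))
        ys.append(synthesize_gt(y_i, y_j, m))
        masks.append(m)
    logits = model.forward_logits(np.stack(xs).astype(np.float32),
                                  train=True)
    p = softmax_foreground(logits)
    dp = np.zeros_like(p)
    loss_sum = 0.0
    for k in range(n_pairs):
        m = masks[k]
        inv = (1 - m).astype(np.uint8)
        for slot, (r1, r2) in ((2 * k, (m, inv)), (2 * k + 1, (inv, m))):
            l1, g1 = seg_loss_grad(p[slot], ys[slot], r1, loss_cfg)
            l2, g2 = seg_loss_grad(p[slot], ys[slot], r2, loss_cfg)
            loss_sum += l1 + loss_cfg.alpha * l2
            dp[slot] = (g1 + loss_cfg.alpha * g2) / n_pairs
    model.zero_grad()
    model.backward(_probability_grad_to_logits(p, dp))
    sgd.step(model, lr)
    return loss_sum / n_pairs


def pretrain(labeled: list[tuple[np.ndarray, np.ndarray]],
             model_cfg: ModelConfig,
             train_cfg: TrainConfig,
             val: list[tuple[np.ndarray, np.ndarray]] | None = None,
             loss_cfg: LossConfig | None = None,
             synthetic_mode: bool = False,
             log_path: str | Path | None = None) -> WeightSet:
    """Supervised pre-training of Θp on labeled images.

    Returns the checkpoint with the highest validation Dice (the final
    weights when no validation split is supplied). ``synthetic_mode``
    switches to copy-paste pre-training among the labeled images, provided
    for comparing the two initialisation strategies.
    """
    if not labeled:
        raise ValueError("labeled set is empty")
    loss_cfg = loss_cfg or LossConfig()
    rngs = _streams(train_cfg.seed)
    model = UNet(model_cfg, seed=int(rngs["init"].integers(2 ** 31)))
    sgd = _SGD(train_cfg)
    log = _Logger(log_path)
    best_dice, best_state = -1.0, None
    total = train_cfg.pretrain_iterations
    try:
        for it in range(total):
            idx = _sample_indices(rngs["data"], len(labeled),
                                  train_cfg.batch_labeled)
            batch = [labeled[int(k)] for k in idx]
            lr = _lr_at(train_cfg, it, total)
            if synthetic_mode:
                loss = _synthetic_pretrain_step(
                    model, sgd, batch, rngs["mask"], train_cfg, loss_cfg, lr)
            else:
                xs = np.stack([x for x, _ in batch]).astype(np.float32)
                loss = _supervised_step(model, sgd, xs,
                                        [y for _, y in batch], loss_cfg, lr)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"pre-training diverged at iteration {it}: loss={loss}")
            record = {"iteration": it, "loss": float(loss)}
            if val and ((it + 1) % train_cfg.eval_every == 0
                        or it + 1 == total):
                dice, jacc = evaluate_checkpoint(model.state(), val)
                record.update(val_dice=dice, val_jaccard=jacc)
                if dice > best_dice:
                    best_dice, best_state = dice, model.state("pretrained")
            log.write(record)
    finally:
        log.close()
    if best_state is None:
        best_state = model.state("pretrained")
    return best_state


def ssl_train(labeled: list[tuple[np.ndarray, np.ndarray]],
              unlabeled: list[np.ndarray],
              pretrained: WeightSet,
              train_cfg: TrainConfig,
              loss_cfg: LossConfig | None = None,
              val: list[tuple[np.ndarray, np.ndarray]] | None = None,
              log_path: str | Path | None = None,
              checkpoint_path: str | Path | None = None) -> WeightSet:
    """Semi-supervised training of the student Θs (Algorithm stage 3).

    Teacher and student both start from ``pretrained``; only the student
    receives gradient updates, the teacher follows by EMA. Returns the
    student checkpoint with the best validation Dice (final student when
    no validation set is given); the student is also the model whose
    validation metrics are logged.
    """
    if not labeled or not unlabeled:
        raise ValueError("both labeled and unlabeled sets must be non-empty")
    loss_cfg = loss_cfg or LossConfig()
    rngs = _streams(train_cfg.seed)
    student = UNet(pretrained.config, seed=0)
    student.load_state(pretrained)
    teacher_ws = pretrained.copy(role="teacher")
    teacher_model = UNet(pretrained.config, seed=0)
    sgd = _SGD(train_cfg)
    log = _Logger(log_path)
    best_dice, best_state = -1.0, None
    total = train_cfg.ssl_iterations
    alpha, gamma = loss_cfg.alpha, loss_cfg.gamma
    try:
        for it in range(total):
            lab_idx = _sample_indices(rngs["data"], len(labeled),
                                      train_cfg.batch_labeled)
            unl_idx = _sample_indices(rngs["data"], len(unlabeled),
                                      train_cfg.batch_unlabeled)
            lab_batch = [labeled[int(k)] for k in lab_idx]
            unl_batch = [unlabeled[int(k)] for k in unl_idx]
            pairs = make_synthetic_batch(lab_batch, unl_batch, teacher_ws,
                                         train_cfg.mask_ratio, rngs["mask"],
                                         model=teacher_model)
            n_pairs = len(pairs)
            xs = np.stack(
                [b.x_in for b in pairs] + [b.x_out for b in pairs]
                + [lab_batch[b.i][0] for b in pairs]
                + [lab_batch[b.j][0] for b in pairs]).astype(np.float32)
            logits = student.forward_logits(xs, train=True)
            p = softmax_foreground(logits)
            dp = np.zeros_like(p)
            sums = {"l_in": 0.0, "l_out": 0.0, "l_i": 0.0, "l_j": 0.0}
            for k, b in enumerate(pairs):
                inv = (1 - b.mask).astype(np.uint8)
                # X_in: labeled-origin region = mask
                l1, g1 = seg_loss_grad(p[k], b.y_in, b.mask, loss_cfg)
                l2, g2 = seg_loss_grad(p[k], b.y_in, inv, loss_cfg)
                sums["l_in"] += l1 + alpha * l2
                dp[k] = (g1 + alpha * g2) / n_pairs
                # X_out: labeled-origin region = complement
                ko = n_pairs + k
                l1, g1 = seg_loss_grad(p[ko], b.y_out, inv, loss_cfg)
                l2, g2 = seg_loss_grad(p[ko], b.y_out, b.mask, loss_cfg)
                sums["l_out"] += l1 + alpha * l2
                dp[ko] = (g1 + alpha * g2) / n_pairs
                # direct supervised loss on the raw labeled images
                ki, kj = 2 * n_pairs + k, 3 * n_pairs + k
                li, gi = seg_loss_grad(p[ki], lab_batch[b.i][1], None,
                                       loss_cfg)
                lj, gj = seg_loss_grad(p[kj], lab_batch[b.j][1], None,
                                       loss_cfg)
                sums["l_i"] += li
                sums["l_j"] += lj
                dp[ki] = gamma * gi / n_pairs
                dp[kj] = gamma * gj / n_pairs
            bundle = total_loss(sums["l_in"] / n_pairs,
                                sums["l_out"] / n_pairs,
                                sums["l_i"] / n_pairs,
                                sums["l_j"] / n_pairs, loss_cfg)
            student.zero_grad()
            student.backward(_probability_grad_to_logits(p, dp))
            sgd.step(student, _lr_at(train_cfg, it, total))
            ema_update(teacher_ws, student.state("student"),
                       train_cfg.ema_lambda)
            record = {"iteration": it, **bundle.as_dict()}
            if val and ((it + 1) % train_cfg.eval_every == 0
                        or it + 1 == total):
                dice, jacc = evaluate_checkpoint(student.state(), val)
                record.update(val_dice=dice, val_jaccard=jacc)
                if dice > best_dice:
                    best_dice, best_state = dice, student.state("student")
            log.write(record)
    finally:
        log.close()
    if best_state is None:
        best_state = student.state("student")
    if checkpoint_path is not None:
        save_checkpoint(checkpoint_path, best_state, iteration=total,
                        val_dice=best_dice if best_dice >= 0 else None)
    return best_state
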