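"""Segmentation metrics and the method-comparison harness.

Dice = 2|A∩B| / (|A|+|B|) and Jaccard = |A∩B| / |A∪B| over binary masks,
reported as per-image means over a validation set (two empty masks agree
perfectly and score 1.0). The harness trains and scores the three
strategies of interest — supervised pre-training only, pure bidirectional
copy-paste (gamma = 0), and the fused objective — across label ratios,
gamma values, channel widths and seeds on the bundled synthetic data.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

METHODS = ("labeled_only", "bcp", "proposed")


def _validate_pair(pred: np.ndarray, gt: np.ndarray):
    pred, gt = np.asarray(pred), np.asarray(gt)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    if not np.isin(pred, (0, 1)).all() or not np.isin(gt, (0, 1)).all():
        raise ValueError("masks must be binary")
    return pred.astype(bool), gt.astype(bool)


def dice_score(pred: np.ndarray, gt: np.ndarray) -> float:
    """2*TP / (2*TP + FP + FN); 1.0 when both masks are empty."""
    pred, gt = _validate_pair(pred, gt)
    tp = int((pred & gt).sum())
    total = int(pred.sum()) + int(gt.sum())
    if total == 0:
        return 1.0
    return 2.0 * tp / total


def jaccard_index(pred: np.ndarray, gt: np.ndarray) -> float:
    """TP / (TP + FP + FN); 1.0 when both masks are empty."""
    pred, gt = _validate_pair(pred, gt)
    inter = int((pred & gt).sum())
    union = int((pred | gt).sum())
    if union == 0:
        return 1.0
    return inter / union


@dataclass
class MetricReport:
    """Rows of (method, label_ratio, gamma, channels, seed, dice, jaccard)."""

    rows: list[dict] = field(default_factory=list)

    def append(self, **kwargs) -> None:
        self.rows.append(kwargs)

    def mean(self, metric: str = "dice", **filters) -> float:
        vals = [r[metric] for r in self.rows
                if all(r.get(k) == v for k, v in filters.items())]
        if not vals:
            raise KeyError(f"no rows match {filters}")
        return float(np.mean(vals))

    def to_csv(self, path: str | Path) -> None:
        if not self.rows:
            raise ValueError("empty report")
        keys = list(self.rows[0])
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=keys)
            writer.writeheader()
            writer.writerows(self.rows)

    def summary(self) -> str:
        lines = [f"{'method':>12} {'ratio':>6} {'gamma':>6} {'ch':>4} "
                 f"{'seed':>5} {'dice':>7} {'jaccard':>8}"]
        for r in self.rows:
            lines.append(
                f"{r['method']:>12} {r['label_ratio']:>6.2f} "
                f"{r['gamma']:>6.2f} {r['channels']:>4d} {r['seed']:>5d} "
                f"{r['dice']:>7.4f} {r['jaccard']:>8.4f}")
        return "\n".join(lines)


def run_comparison(methods=METHODS,
                   label_ratios=(0.05,),
                   seeds=(0,),
                   gammas=None,
                   channels=None,
                   synth_cfg=None,
                   model_cfg=None,
                   train_cfg=None,
                   loss_cfg=None,
                   val_fraction: float = 0.2,
                   csv_path: str | Path | None = None) -> MetricReport:
    """Train and evaluate each (method, label_ratio, seed[, gamma,
    channel]) combination on freshly generated synthetic data.

    Pre-training is shared between methods that agree on data, seed and
    architecture; the ``labeled_only`` row scores Θp itself. ``gammas``
    expands the ``proposed`` method into one row per gamma; ``channels``
    sweeps the first-encoder width.
    """
    from .losses import LossConfig
    from .model import ModelConfig
    from .synthetic import SynthConfig, generate_dataset
    from .trainer import TrainConfig, evaluate_checkpoint, pretrain, ssl_train

    synth_cfg = synth_cfg or SynthConfig()
    model_cfg = model_cfg or ModelConfig(first_encoder_channels=8)
    train_cfg = train_cfg or TrainConfig()
    loss_cfg = loss_cfg or LossConfig()
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    channel_list = list(channels) if channels else \
        [model_cfg.first_encoder_channels]
    report = MetricReport()

    for seed in seeds:
        for ratio in label_ratios:
            data = generate_dataset(
                replace(synth_cfg, seed=synth_cfg.seed + 1000 * seed),
                label_ratio=ratio, val_fraction=val_fraction)
            for ch in channel_list:
                mcfg = replace(model_cfg, first_encoder_channels=ch)
                tcfg = replace(train_cfg, seed=seed, label_ratio=ratio)
                theta_p = pretrain(data.labeled, mcfg, tcfg,
                                   val=data.val, loss_cfg=loss_cfg)
                variants = []
                if "labeled_only" in methods:
                    variants.append(("labeled_only", None))
                if "bcp" in methods:
                    variants.append(("bcp", 0.0))
                if "proposed" in methods:
                    for g in (gammas or [loss_cfg.gamma]):
                        variants.append(("proposed", float(g)))
                for method, gamma in variants:
                    if gamma is None:
                        weights = theta_p
                        gamma_out = 0.0
                    else:
                        lcfg = replace(loss_cfg, gamma=gamma)
                        weights = ssl_train(data.labeled, data.unlabeled,
                                            theta_p, tcfg, lcfg,
                                            val=data.val)
                        gamma_out = gamma
                    dice, jacc = evaluate_checkpoint(weights, data.val)
                    report.append(method=method, label_ratio=float(ratio),
                                  gamma=gamma_out, channels=int(ch),
                                  seed=int(seed), dice=dice, jaccard=jacc)
    if csv_path is not None:
        report.to_csv(csv_path)
    return report


def desk_benchmark(seeds=(0, 1, 2),
                   methods=METHODS,
                   csv_path: str | Path | None = None) -> MetricReport:
    """The bundled desk-scale benchmark: 64 px patches, 200 train / 50
    validation images, 5% label ratio, an 8-channel U-Net and 300 + 300
    training iterations per method and seed.

    Every patch is a lesion-centred crop (1-3 lesions), mirroring how real
    acne patches are cropped around lesion sites. This is the scaled-down
    analogue of the full-resolution protocol; full-scale settings are
    reachable through the same configs.
    """
    from .losses import LossConfig
    from .model import ModelConfig
    from .synthetic import SynthConfig
    from .trainer import TrainConfig

    synth_cfg = SynthConfig(image_size=64, n_images=250,
                            lesions_per_image=(1, 3), seed=0)
    model_cfg = ModelConfig(first_encoder_channels=8, depth=4)
    train_cfg = TrainConfig(pretrain_iterations=300, ssl_iterations=300,
                            eval_every=50)
    return run_comparison(methods=methods, label_ratios=(0.05,),
                          seeds=tuple(seeds), synth_cfg=synth_cfg,
                          model_cfg=model_cfg, train_cfg=train_cfg,
                          loss_cfg=LossConfig(), val_fraction=0.2,
                          csv_path=csv_path)
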