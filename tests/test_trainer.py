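"""EMA updates, the two training stages, determinism, gradient isolation."""

import json

import numpy as np
import pytest

from bcpseg import LossConfig, ModelConfig, TrainConfig
from bcpseg.model import init_model
from bcpseg.trainer import ema_update, evaluate_checkpoint, pretrain, ssl_train


class TestEmaUpdate:
    def _pair(self):
        cfg = ModelConfig(2, depth=2)
        return init_model(cfg, 0).copy("teacher"), \
            init_model(cfg, 1).copy("student")

    def test_lambda_one_freezes_teacher(self):
        t, s = self._pair()
        before = t.fingerprint()
        ema_update(t, s, 1.0)
        assert t.fingerprint() == before

    def test_lambda_zero_copies_student(self):
        t, s = self._pair()
        ema_update(t, s, 0.0)
        for k in t.params:
            assert np.allclose(t.params[k], s.params[k])
        for k in t.buffers:
            assert np.allclose(t.buffers[k], s.buffers[k])

    def test_scalar_arithmetic(self):
        t, s = self._pair()
        k = next(iter(t.params))
        t.params[k][...] = 1.0
        s.params[k][...] = 0.0
        ema_update(t, s, 0.99)
        assert np.allclose(t.params[k], 0.99)

    @pytest.mark.parametrize("lam", [0.0, 0.5, 0.99, 1.0])
    def test_repeated_updates_follow_geometric_recursion(self, lam):
        """k updates with a frozen student give
        lam**k * theta0 + (1 - lam**k) * student, to 1e-10 (the update is
        dtype-generic; float64 state isolates the algebra from rounding)."""
        t, s = self._pair()
        for ws in (t, s):
            for group in (ws.params, ws.buffers):
                for k in group:
                    group[k] = group[k].astype(np.float64)
        t0 = {k: v.copy() for k, v in t.items()}
        for _ in range(100):
            ema_update(t, s, lam)
        for k in t.params:
            expected = lam ** 100 * t0[k] + (1 - lam ** 100) * s.params[k]
            assert np.abs(t.params[k] - expected).max() < 1e-10

    def test_mismatched_sets_rejected(self):
        t, _ = self._pair()
        other = init_model(ModelConfig(4, depth=2), 0).copy("student")
        with pytest.raises(ValueError):
            ema_update(t, other, 0.5)
        with pytest.raises(ValueError):
            ema_update(t, t.copy("student"), 1.5)


class TestPretrain:
    def test_zero_iterations_returns_initial_weights(self, tiny_dataset,
                                                     tiny_model_cfg):
        cfg = TrainConfig(pretrain_iterations=0, seed=4)
        got = pretrain(tiny_dataset.labeled, tiny_model_cfg, cfg)
        again = pretrain(tiny_dataset.labeled, tiny_model_cfg, cfg)
        assert got.fingerprint() == again.fingerprint()
        trained = pretrain(tiny_dataset.labeled, tiny_model_cfg,
                           TrainConfig(pretrain_iterations=2,
                                       batch_labeled=4, seed=4))
        assert trained.fingerprint() != got.fingerprint()

    def test_training_beats_untrained_model(self):
        """50 labeled 64-px images, 8-channel U-Net, 200 iterations: the
        pre-trained checkpoint must clearly outscore random init."""
        from bcpseg import SynthConfig, generate_dataset

        data = generate_dataset(
            SynthConfig(image_size=64, n_images=63,
                        lesions_per_image=(1, 3), seed=21),
            label_ratio=1.0, val_fraction=0.2)
        mcfg = ModelConfig(first_encoder_channels=8, depth=4)
        cfg = TrainConfig(pretrain_iterations=200, eval_every=40, seed=0)
        trained = pretrain(data.labeled, mcfg, cfg, val=data.val)
        untrained = pretrain(data.labeled, mcfg,
                             TrainConfig(pretrain_iterations=0, seed=0))
        dice_trained, _ = evaluate_checkpoint(trained, data.val)
        dice_untrained, _ = evaluate_checkpoint(untrained, data.val)
        assert dice_trained > dice_untrained

    def test_synthetic_pretraining_mode_runs_and_logs(self, tiny_dataset,
                                                      tiny_model_cfg,
                                                      tmp_path):
        log = tmp_path / "log.jsonl"
        cfg = TrainConfig(pretrain_iterations=6, batch_labeled=4,
                          eval_every=3, seed=1)
        ws = pretrain(tiny_dataset.labeled, tiny_model_cfg, cfg,
                      val=tiny_dataset.val, synthetic_mode=True,
                      log_path=log)
        records = [json.loads(line) for line in log.read_text().splitlines()]
        assert len(records) == 6
        assert all(np.isfinite(r["loss"]) for r in records)
        assert any("val_dice" in r for r in records)
        assert ws.role == "pretrained"

    def test_empty_labeled_set_rejected(self, tiny_model_cfg):
        with pytest.raises(ValueError):
            pretrain([], tiny_model_cfg, TrainConfig())


@pytest.fixture(scope="module")
def theta_p(tiny_dataset, tiny_model_cfg):
    cfg = TrainConfig(pretrain_iterations=30, batch_labeled=8,
                      eval_every=15, seed=0)
    return pretrain(tiny_dataset.labeled, tiny_model_cfg, cfg,
                    val=tiny_dataset.val)


class TestSslTrain:
    def test_zero_learning_rate_is_a_fixed_point(self, tiny_dataset,
                                                 theta_p):
        cfg = TrainConfig(ssl_iterations=1, batch_labeled=4,
                          batch_unlabeled=4, learning_rate=0.0, seed=2)
        student = ssl_train(tiny_dataset.labeled, tiny_dataset.unlabeled,
                            theta_p, cfg, LossConfig())
        for k in student.params:
            assert np.array_equal(student.params[k], theta_p.params[k]), k

    def test_run_is_deterministic(self, tiny_dataset, theta_p, tmp_path):
        cfg = TrainConfig(ssl_iterations=8, batch_labeled=4,
                          batch_unlabeled=4, eval_every=4, seed=5)
        results = []
        for tag in ("a", "b"):
            log = tmp_path / f"log_{tag}.jsonl"
            ws = ssl_train(tiny_dataset.labeled, tiny_dataset.unlabeled,
                           theta_p, cfg, LossConfig(),
                           val=tiny_dataset.val, log_path=log)
            results.append((ws.fingerprint(), log.read_text()))
        assert results[0] == results[1]

    def test_loss_components_logged_and_finite(self, tiny_dataset, theta_p,
                                               tmp_path):
        log = tmp_path / "log.jsonl"
        cfg = TrainConfig(ssl_iterations=5, batch_labeled=4,
                          batch_unlabeled=4, eval_every=5, seed=3)
        ssl_train(tiny_dataset.labeled, tiny_dataset.unlabeled, theta_p,
                  cfg, LossConfig(), val=tiny_dataset.val, log_path=log)
        records = [json.loads(line) for line in log.read_text().splitlines()]
        assert len(records) == 5
        for r in records:
            for key in ("l_in", "l_out", "l_i", "l_j", "total"):
                assert np.isfinite(r[key])
            assert r["total"] == pytest.approx(
                r["l_in"] + r["l_out"] + 0.5 * (r["l_i"] + r["l_j"]),
                rel=1e-6)

    def test_gamma_zero_drops_labeled_loss_from_total(self, tiny_dataset,
                                                      theta_p, tmp_path):
        log = tmp_path / "log.jsonl"
        cfg = TrainConfig(ssl_iterations=3, batch_labeled=4,
                          batch_unlabeled=4, seed=3)
        ssl_train(tiny_dataset.labeled, tiny_dataset.unlabeled, theta_p,
                  cfg, LossConfig(gamma=0.0), log_path=log)
        for line in log.read_text().splitlines():
            r = json.loads(line)
            assert r["total"] == pytest.approx(r["l_in"] + r["l_out"],
                                               rel=1e-6)

    def test_best_checkpoint_dice_non_decreasing_in_log(self, tiny_dataset,
                                                        theta_p, tmp_path):
        log = tmp_path / "log.jsonl"
        cfg = TrainConfig(ssl_iterations=20, batch_labeled=4,
                          batch_unlabeled=4, eval_every=5, seed=1)
        best = ssl_train(tiny_dataset.labeled, tiny_dataset.unlabeled,
                         theta_p, cfg, LossConfig(),
                         val=tiny_dataset.val, log_path=log)
        dices = [json.loads(line)["val_dice"]
                 for line in log.read_text().splitlines()
                 if "val_dice" in json.loads(line)]
        running_best = np.maximum.accumulate(dices)
        assert (np.diff(running_best) >= 0).all()
        best_dice, _ = evaluate_checkpoint(best, tiny_dataset.val)
        assert best_dice == pytest.approx(max(dices), abs=1e-9)

    def test_logged_losses_match_independent_recomputation(self,
                                                           tiny_dataset,
                                                           theta_p,
                                                           tmp_path):
        """Replay the first gamma=0 iteration outside the trainer: same
        seeded streams, same batch composition, but losses computed with
        the per-pixel loop oracle. The logged L_in + L_out must match."""
        from test_losses import seg_loss_oracle

        from bcpseg.bcp import make_synthetic_batch
        from bcpseg.model import UNet, softmax_foreground
        from bcpseg.trainer import _sample_indices, _streams

        cfg = TrainConfig(ssl_iterations=1, batch_labeled=4,
                          batch_unlabeled=4, seed=11)
        lcfg = LossConfig(gamma=0.0)
        log = tmp_path / "log.jsonl"
        ssl_train(tiny_dataset.labeled, tiny_dataset.unlabeled, theta_p,
                  cfg, lcfg, log_path=log)
        logged = json.loads(log.read_text().splitlines()[0])

        rngs = _streams(cfg.seed)
        lab_idx = _sample_indices(rngs["data"], len(tiny_dataset.labeled),
                                  cfg.batch_labeled)
        unl_idx = _sample_indices(rngs["data"],
                                  len(tiny_dataset.unlabeled),
                                  cfg.batch_unlabeled)
        lab = [tiny_dataset.labeled[int(k)] for k in lab_idx]
        unl = [tiny_dataset.unlabeled[int(k)] for k in unl_idx]
        pairs = make_synthetic_batch(lab, unl, theta_p, cfg.mask_ratio,
                                     rngs["mask"])
        student = UNet(theta_p.config, seed=0)
        student.load_state(theta_p)
        xs = np.stack([b.x_in for b in pairs] + [b.x_out for b in pairs]
                      + [lab[b.i][0] for b in pairs]
                      + [lab[b.j][0] for b in pairs]).astype(np.float32)
        p = softmax_foreground(student.forward_logits(xs, train=True))
        n = len(pairs)
        l_in = l_out = 0.0
        for k, b in enumerate(pairs):
            inv = (1 - b.mask).astype(np.uint8)
            l_in += (seg_loss_oracle(p[k], b.y_in, b.mask, lcfg)
                     + lcfg.alpha * seg_loss_oracle(p[k], b.y_in, inv,
                                                    lcfg))
            l_out += (seg_loss_oracle(p[n + k], b.y_out, inv, lcfg)
                      + lcfg.alpha * seg_loss_oracle(p[n + k], b.y_out,
                                                     b.mask, lcfg))
        assert logged["l_in"] == pytest.approx(l_in / n, abs=1e-6)
        assert logged["l_out"] == pytest.approx(l_out / n, abs=1e-6)
        assert logged["total"] == pytest.approx((l_in + l_out) / n,
                                                abs=1e-6)

    def test_teacher_forward_never_mutates_weights(self, tiny_dataset,
                                                   theta_p, rng):
        """Pseudo-labeling is pure inference: composing synthetic batches
        leaves the teacher weight set bit-identical."""
        from bcpseg.bcp import make_synthetic_batch

        teacher = theta_p.copy("teacher")
        before = teacher.fingerprint()
        make_synthetic_batch(tiny_dataset.labeled[:4],
                             tiny_dataset.unlabeled[:4],
                             teacher, 2 / 3, rng)
        assert teacher.fingerprint() == before

    def test_empty_sets_rejected(self, theta_p, tiny_dataset):
        with pytest.raises(ValueError):
            ssl_train([], tiny_dataset.unlabeled, theta_p, TrainConfig())
        with pytest.raises(ValueError):
            ssl_train(tiny_dataset.labeled, [], theta_p, TrainConfig())


def test_train_config_validation():
    with pytest.raises(ValueError):
        TrainConfig(ema_lambda=1.2)
    with pytest.raises(ValueError):
        TrainConfig(batch_labeled=7)
    with pytest.raises(ValueError):
        TrainConfig(mask_ratio=0.0)
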