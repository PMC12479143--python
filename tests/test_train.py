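"""Training loop, schedule, checkpoint selection and serialisation."""

import numpy as np
import pytest

from hypersar import (
    SarpNet,
    SarpNetConfig,
    TrainConfig,
    UNet1D,
    UNet1DConfig,
    enhance_field,
    load_checkpoint,
    predict_field,
    save_checkpoint,
    split_dataset,
    train_stage,
)
from hypersar.errors import InvalidArgumentError
from hypersar.nn import step_lr

SMALL = SarpNetConfig(embed_dim=32, d_k=32, n_blocks=2, decoder_widths=(64, 32))


class TestSchedule:
    def test_decay_every_100_epochs(self):
        """lr is constant within a 100-epoch block and drops by 0.2 across."""
        assert step_lr(1e-4, 1) == pytest.approx(1e-4)
        assert step_lr(1e-4, 99) == pytest.approx(1e-4)
        assert step_lr(1e-4, 100) == pytest.approx(1e-4)
        assert step_lr(1e-4, 101) == pytest.approx(0.2 * step_lr(1e-4, 99))
        assert step_lr(1e-4, 201) == pytest.approx(1e-4 * 0.2**2)

    def test_custom_interval(self):
        assert step_lr(1.0, 5, factor=0.5, every=2) == 0.5**2

    def test_epoch_is_one_based(self):
        with pytest.raises(ValueError):
            step_lr(1e-4, 0)


class TestTrainStage:
    def test_history_and_lr_schedule(self, records):
        train, val, _ = split_dataset(records, (5, 2, 0), seed=0)
        net = SarpNet(SMALL, seed=0)
        cfg = TrainConfig(lr=1e-3, epochs=3, batch_size=2, decay_every=2, seed=1)
        history = train_stage(net, train, val, cfg)
        assert len(history) == 3
        assert history[0]["lr"] == pytest.approx(1e-3)
        assert history[2]["lr"] == pytest.approx(0.2e-3)
        assert all(np.isfinite(h["train_loss"]) for h in history)
        assert all(np.isfinite(h["val_loss"]) for h in history)

    def test_training_reduces_loss(self, records):
        train, val, _ = split_dataset(records, (6, 2, 0), seed=0)
        net = SarpNet(SMALL, seed=0)
        cfg = TrainConfig(lr=1e-3, epochs=8, batch_size=2, seed=1)
        history = train_stage(net, train, val, cfg)
        assert history[-1]["train_loss"] < history[0]["train_loss"]

    def test_empty_training_set_rejected(self, records):
        with pytest.raises(InvalidArgumentError):
            train_stage(SarpNet(SMALL, seed=0), [], records[:1], TrainConfig(epochs=1))

    def test_enhance_stage_on_signals(self, records, rng):
        train_pairs = [(r.brain_sar + rng.normal(0, 2, r.n_points), r.brain_sar) for r in records[:5]]
        val_pairs = [(r.brain_sar + rng.normal(0, 2, r.n_points), r.brain_sar) for r in records[5:7]]
        net = UNet1D(UNet1DConfig(base_channels=4), seed=0)
        history = train_stage(net, train_pairs, val_pairs, TrainConfig(lr=1e-3, epochs=3, seed=2))
        assert len(history) == 3

    def test_enhancer_keeps_identity_unless_validated(self, records, rng):
        """With val-RMSE selection, an enhancer whose training never improves
        the validation RMSE returns its identity initialisation."""
        # targets are pure noise, unrelated to inputs: training cannot help
        train_pairs = [
            (r.brain_sar, rng.normal(50, 20, r.n_points)) for r in records[:4]
        ]
        val_pairs = [(r.brain_sar, r.brain_sar) for r in records[4:6]]  # identity is optimal
        net = UNet1D(UNet1DConfig(base_channels=4), seed=0)
        train_stage(
            net, train_pairs, val_pairs, TrainConfig(lr=1e-3, epochs=3, seed=2, select_on="val_rmse")
        )
        x = records[0].brain_sar
        assert np.allclose(net.refine(x), x, atol=1e-9)

    def test_deterministic_given_seed(self, records):
        train, val, _ = split_dataset(records, (4, 2, 0), seed=0)
        outs = []
        for _ in range(2):
            net = SarpNet(SMALL, seed=3)
            train_stage(net, train, val, TrainConfig(lr=1e-3, epochs=2, seed=7))
            outs.append(predict_field(net, val[0]).values)
        assert np.array_equal(outs[0], outs[1])


class TestFieldWrappers:
    def test_predict_field_zero_outside_brain(self, records):
        net = SarpNet(seed=0)
        f = predict_field(net, records[0])
        bm = records[0].sar_truth.phantom.brain_mask
        assert np.all(f.values[~bm] == 0)
        assert np.all(f.values >= 0)

    def test_enhance_field_untrained_is_identity(self, records):
        net = SarpNet(seed=0)
        f = predict_field(net, records[0])
        e = enhance_field(UNet1D(seed=0), f)
        assert np.allclose(e.values, f.values, atol=1e-9)


class TestCheckpoints:
    def test_sarpnet_round_trip(self, tmp_path, records):
        net = SarpNet(SarpNetConfig(n_blocks=2, decoder_widths=(64, 32)), seed=5)
        path = tmp_path / "p.npz"
        save_checkpoint(str(path), net, TrainConfig(epochs=1))
        back = load_checkpoint(str(path))
        r = records[0]
        assert np.allclose(
            back.predict(r.normalized_inputs, r.phases.flat),
            net.predict(r.normalized_inputs, r.phases.flat),
        )

    def test_unet_round_trip(self, tmp_path, rng):
        net = UNet1D(UNet1DConfig(base_channels=4), seed=5)
        # perturb so it is not the identity
        for p in net.parameters():
            p.data = p.data + rng.normal(0, 0.05, p.data.shape)
        path = tmp_path / "e.npz"
        save_checkpoint(str(path), net)
        back = load_checkpoint(str(path))
        sig = rng.random(100) * 40
        assert np.allclose(back.refine(sig), net.refine(sig))
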