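import numpy as np
import pytest

from flowerseg.cnn import (
    NetConfig,
    Network,
    TrainConfig,
    build_network,
    load_checkpoint,
    predict_patch,
    save_checkpoint,
    softmax_xent,
    train,
)

from conftest import make_separable_manifest

TINY = NetConfig(conv_blocks=[(1, 4)], fc_widths=[8, 2])


class TestConfig:
    def test_last_fc_width_must_be_two(self):
        with pytest.raises(ValueError):
            NetConfig(fc_widths=[64, 3])

    def test_pooling_cascade_exhaustion_names_block(self):
        cfg = NetConfig(conv_blocks=[(1, 4)] * 5, input_size=31)
        with pytest.raises(ValueError, match="block 4"):
            Network.initialize(cfg, seed=0)


class TestBuild:
    def test_forward_emits_two_scores(self, rng):
        net = build_network(NetConfig(), seed=0)
        x = rng.random((3, 31, 31, 3))
        assert net.forward(x).shape == (3, 2)

    def test_same_seed_identical_parameters(self):
        a = build_network(seed=5)
        b = build_network(seed=5)
        assert all(np.array_equal(a.params[k], b.params[k]) for k in a.params)

    def test_gaussian_init_moments(self):
        # fixed sigma=0.01 recipe: sample moments over >1e5 draws, 3 SE bands
        net = build_network(NetConfig(), seed=0, init_std=0.01)
        w = np.concatenate(
            [v.ravel() for k, v in net.params.items() if k.endswith("_W")]
        )
        n = w.size
        assert n >= 1e5
        assert abs(w.mean()) < 3 * 0.01 / np.sqrt(n)
        assert abs(w.std() - 0.01) < 3 * 0.01 / np.sqrt(2 * n)

    def test_biases_zero(self):
        net = build_network(seed=1)
        assert all(
            (v == 0).all() for k, v in net.params.items() if k.endswith("_b")
        )


class TestPredict:
    def test_zero_weights_score_half_label_negative(self):
        net = Network.initialize(TINY, seed=0)
        for k in net.params:
            net.params[k] = np.zeros_like(net.params[k])
        block = np.random.default_rng(0).integers(0, 256, (31, 31, 3)).astype(np.uint8)
        label, score = predict_patch(net, block)
        assert score == 0.5
        assert label == "negative"  # tie resolves to negative

    def test_score_invariant_to_logit_shift(self, rng):
        net = Network.initialize(TINY, seed=3)
        block = rng.integers(0, 256, (31, 31, 3)).astype(np.uint8)
        _, s0 = predict_patch(net, block)
        net.params["fc1_b"] = net.params["fc1_b"] + 17.0  # shifts both logits
        _, s1 = predict_patch(net, block)
        assert s1 == pytest.approx(s0, abs=1e-12)

    def test_shape_mismatch_rejected(self, rng):
        net = Network.initialize(TINY, seed=0)
        with pytest.raises(ValueError):
            net.predict_proba(rng.integers(0, 256, (1, 15, 15, 3)))


class TestGradients:
    def test_backprop_matches_finite_differences(self, rng):
        """Hand-rolled backprop vs central finite differences, 4-sample batch."""
        net = Network.initialize(TINY, seed=7)
        x = rng.random((4, 31, 31, 3))
        y = np.array([0, 1, 1, 0])

        logits, cache = net.forward(x, want_cache=True)
        _, dlogits = softmax_xent(logits, y)
        grads = net.backward(dlogits, cache)

        def loss_at():
            return softmax_xent(net.forward(x), y)[0]

        eps = 1e-6
        check_rng = np.random.default_rng(0)
        for name in net.params:
            flat = net.params[name].ravel()
            for idx in check_rng.choice(flat.size, size=min(5, flat.size), replace=False):
                orig = flat[idx]
                flat[idx] = orig + eps
                lp = loss_at()
                flat[idx] = orig - eps
                lm = loss_at()
                flat[idx] = orig
                num = (lp - lm) / (2 * eps)
                ana = grads[name].ravel()[idx]
                denom = max(abs(num), abs(ana), 1e-8)
                assert abs(num - ana) / denom < 1e-3, f"{name}[{idx}]: {num} vs {ana}"


class TestTraining:
    def test_single_class_rejected(self):
        manifest = make_separable_manifest(5)
        manifest.samples = [s for s in manifest.samples if s.label == "positive"]
        net = Network.initialize(TINY, seed=0)
        with pytest.raises(ValueError):
            train(net, manifest)

    def test_reproducible_record(self):
        manifest = make_separable_manifest(20)
        recs = []
        for _ in range(2):
            net = Network.initialize(TINY, seed=3)
            _, rec = train(net, manifest, TrainConfig(seed=3, max_steps=4))
            recs.append(rec)
        assert recs[0].train_loss == recs[1].train_loss
        assert recs[0].val_error == recs[1].val_error

    def test_loss_decreases_early(self):
        manifest = make_separable_manifest(50)
        net = Network.initialize(NetConfig(), seed=0)
        _, rec = train(net, manifest, TrainConfig(seed=0, max_steps=5))
        drops = sum(
            rec.train_loss[i + 1] < rec.train_loss[i] for i in range(4)
        )
        assert drops >= 3  # monotone trend, one slack step

    def test_lr_schedule_non_increasing_with_exact_decade_drops(self):
        manifest = make_separable_manifest(40)
        net = Network.initialize(NetConfig(), seed=1)
        _, rec = train(
            net, manifest, TrainConfig(seed=1, max_steps=15, plateau_patience=2)
        )
        lrs = rec.learning_rate
        assert all(b <= a for a, b in zip(lrs, lrs[1:]))
        for a, b in zip(lrs, lrs[1:]):
            ratio = b / a
            assert ratio == pytest.approx(1.0) or ratio == pytest.approx(0.1)


class TestCheckpoints:
    def test_round_trip(self, rng, tmp_path):
        net = Network.initialize(TINY, seed=2)
        path = save_checkpoint(net, tmp_path / "model.ckpt")
        back = load_checkpoint(path)
        assert back.cfg.conv_blocks == net.cfg.conv_blocks
        x = rng.random((2, 31, 31, 3))
        assert np.allclose(net.forward(x), back.forward(x))
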