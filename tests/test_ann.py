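"""Reconstruction networks: architecture, loss oracle, training contracts."""

import numpy as np
import pytest

from cceit import nn
from cceit.ann import (
    CganConfig,
    FcnnConfig,
    GanLossTerms,
    PatchDiscriminator,
    UnetGenerator,
    build_fcnn,
    fcnn_parameter_count,
    generator_loss,
    load_model,
    measurements_to_condition,
    reconstruct_cgan,
    reconstruct_fcnn,
    save_model,
    train_cgan,
    train_fcnn,
)
from cceit.geometry import Grid, build_fov_mask, build_measurement_index

TINY_CGAN = CganConfig(enc_channels=(4, 8, 16, 32), batch_size=16, epochs=2, seed=0)


class TestFcnnArchitecture:
    def test_output_length_matches_fov(self):
        model = build_fcnn(FcnnConfig())
        x = np.random.default_rng(0).standard_normal((3, 992)).astype(np.float32)
        y = model.forward(x, training=True)
        assert y.shape == (3, 1856)

    def test_parameter_count_formula(self):
        cfg = FcnnConfig(input_size=992, hidden_size=1856, output_size=1856)
        expected = 992 * 1856 + 1856 + 1856 * 1856 + 1856 + 2 * 992 + 2 * 1856
        assert fcnn_parameter_count(cfg) == expected
        counted = sum(p.size for _, p, _ in build_fcnn(cfg).params())
        assert counted == expected

    def test_layer_sequence(self):
        model = build_fcnn(FcnnConfig())
        kinds = [type(l).__name__ for l in model.layers]
        assert kinds == ["BatchNorm", "Dense", "BatchNorm", "ReLU", "Dense"]

    def test_eval_mode_deterministic_and_finite(self):
        model = build_fcnn(FcnnConfig(input_size=16, hidden_size=8, output_size=4))
        x = np.zeros((2, 16), np.float32)
        a = model.forward(x, training=False)
        b = model.forward(x, training=False)
        assert np.array_equal(a, b)
        assert np.all(np.isfinite(a))


class TestGeneratorLoss:
    def test_perfect_generator_loss_vanishes(self):
        y = np.random.default_rng(0).random((4, 10))
        terms = GanLossTerms(l_r=1.0, l_p=np.array([1 - 1e-12]), y_r=y, y_p=y.copy())
        assert generator_loss(terms) < 1e-9

    def test_cross_entropy_term_alone(self):
        y = np.random.default_rng(1).random(8)
        terms = GanLossTerms(l_r=1.0, l_p=np.array([0.5]), y_r=y, y_p=y.copy())
        assert np.isclose(generator_loss(terms), 0.6931, atol=1e-4)

    def test_all_three_terms(self):
        y_r = np.full(25, 0.6)
        y_p = np.full(25, 0.5)  # uniform difference 0.1
        terms = GanLossTerms(l_r=1.0, l_p=np.array([0.5]), y_r=y_r, y_p=y_p)
        assert np.isclose(generator_loss(terms), 11.6931, atol=1e-4)

    def test_matches_hand_computed_sum_on_random_tensors(self):
        rng = np.random.default_rng(2)
        y_r, y_p = rng.random(40), rng.random(40)
        l_p = np.array([0.37])
        got = generator_loss(GanLossTerms(1.0, l_p, y_r, y_p))
        expected = (
            -np.log(0.37)
            + 100 * np.mean((y_r - y_p) ** 2)
            + 100 * np.mean(np.abs(y_r - y_p))
        )
        assert np.isclose(got, expected, atol=1e-9)

    def test_probability_outside_unit_interval_rejected(self):
        y = np.zeros(4)
        with pytest.raises(ValueError):
            generator_loss(GanLossTerms(1.0, np.array([1.5]), y, y))


class TestTrainFcnn:
    def test_overfits_small_sample(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((200, 992)).astype(np.float32)
        W = rng.standard_normal((992, 1856)).astype(np.float32) * 0.03
        y = np.tanh(x @ W)
        cfg = FcnnConfig(epochs=60, seed=1, lr=1e-3)
        model, hist = train_fcnn(x, y, cfg, val_ratio=0.1)
        assert hist.train_loss[-1] < hist.train_loss[0] / 10

    def test_identical_seeds_give_identical_weights(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal((96, 992)).astype(np.float32)
        y = rng.standard_normal((96, 1856)).astype(np.float32)
        cfg = FcnnConfig(epochs=2, seed=9)
        m1, _ = train_fcnn(x, y, cfg)
        m2, _ = train_fcnn(x, y, cfg)
        for (_, p1, _), (_, p2, _) in zip(m1.params(), m2.params()):
            assert np.array_equal(p1, p2)

    def test_batch_inference_preserves_order(self):
        model = build_fcnn(FcnnConfig())
        x = np.random.default_rng(5).standard_normal((6, 992)).astype(np.float32)
        batch = reconstruct_fcnn(model, x)
        single = np.stack([reconstruct_fcnn(model, x[i : i + 1])[0] for i in range(6)])
        assert np.allclose(batch, single, atol=1e-5)


class TestCgan:
    @pytest.fixture(scope="class")
    def geometry(self):
        grid = Grid(fine_n=64)
        return build_fov_mask(grid), build_measurement_index(32)

    def test_generator_output_is_64x64_masked_to_fov(self, geometry):
        fov, index = geometry
        G = UnetGenerator(TINY_CGAN, np.random.default_rng(0))
        cond = np.random.default_rng(1).random((2, 1, 32, 32)).astype(np.float32)
        img = G.forward(cond, training=False)
        assert img.shape == (2, 1, 64, 64)
        x = np.random.default_rng(2).random((2, 992))
        out = reconstruct_cgan(G, x, fov, index)
        assert out.shape == (2, fov.n_fov)

    def test_untrained_discriminator_sits_near_half(self, geometry):
        _, index = geometry
        D = PatchDiscriminator(np.random.default_rng(3))
        cond = np.random.default_rng(4).random((8, 1, 32, 32)).astype(np.float32)
        img = np.random.default_rng(5).random((8, 1, 64, 64)).astype(np.float32)
        p = D.forward((cond, img), training=False)
        assert np.all(np.abs(p - 0.5) < 0.2)

    def test_eval_mode_inference_is_deterministic(self, geometry):
        fov, index = geometry
        G = UnetGenerator(TINY_CGAN, np.random.default_rng(6))
        x = np.random.default_rng(7).random((3, 992))
        a = reconstruct_cgan(G, x, fov, index)
        b = reconstruct_cgan(G, x, fov, index)
        assert np.array_equal(a, b)

    def test_short_training_runs_and_is_seeded(self, geometry):
        fov, index = geometry
        rng = np.random.default_rng(8)
        x = rng.random((32, 992)).astype(np.float32)
        y = rng.random((32, fov.n_fov)).astype(np.float32) * 0.2
        G1, h1 = train_cgan(x, y, fov, index, TINY_CGAN)
        G2, h2 = train_cgan(x, y, fov, index, TINY_CGAN)
        assert h1.train_loss == h2.train_loss
        for (_, p1, _), (_, p2, _) in zip(G1.params(), G2.params()):
            assert np.array_equal(p1, p2)

    def test_condition_matrix_layout(self, geometry):
        _, index = geometry
        x = np.arange(992, dtype=np.float32)[None]
        cond = measurements_to_condition(x, index)
        assert cond.shape == (1, 1, 32, 32)
        assert cond[0, 0, 0, 0] == 0  # diagonal stays zero


class TestPersistence:
    def test_fcnn_roundtrip(self, tmp_path):
        cfg = FcnnConfig(input_size=16, hidden_size=8, output_size=4, seed=2)
        model = build_fcnn(cfg)
        x = np.random.default_rng(0).standard_normal((3, 16)).astype(np.float32)
        before = model.forward(x, training=False)
        path = str(tmp_path / "m.npz")
        save_model(path, "fcnn", model, cfg)
        kind, back, cfg2 = load_model(path)
        assert kind == "fcnn"
        assert np.array_equal(back.forward(x, training=False), before)

    def test_cgan_roundtrip(self, tmp_path):
        from cceit.ann import build_generator

        G = build_generator(TINY_CGAN, np.random.default_rng(1))
        cond = np.random.default_rng(2).random((2, 1, 32, 32)).astype(np.float32)
        before = G.forward(cond, training=False)
        path = str(tmp_path / "g.npz")
        save_model(path, "cgan", G, TINY_CGAN)
        _, back, _ = load_model(path)
        assert np.array_equal(back.forward(cond, training=False), before)
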