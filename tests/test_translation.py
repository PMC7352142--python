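"""Adversarial losses, network contracts, checkpointing, training dynamics."""

import numpy as np
import pytest

from cyclereg import (ImageGrid, TrainConfig, adversarial_loss,
                      build_discriminator, build_generator, cycle_loss,
                      extract_patches, load_model, normalize_intensity,
                      save_model, train_cyclegan, translate)
from cyclereg.translation import GeneratorSpec, TranslationModel


class TestAdversarialLoss:
    def test_perfect_discriminator_scores_zero(self):
        for alpha in (0.0, 0.5, 1.0, 3.0):
            assert adversarial_loss(1.0, 0.0, 1.0, 0.0, alpha) == 0.0

    def test_all_half_scores_alpha_one(self):
        assert adversarial_loss(0.5, 0.5, 0.5, 0.5, 1.0) == pytest.approx(1.0)

    def test_all_half_scores_alpha_half(self):
        assert adversarial_loss(0.5, 0.5, 0.5, 0.5, 0.5) == pytest.approx(0.75)

    def test_matches_hand_computation_on_arrays(self, rng):
        r1, f1, r2, f2 = (rng.random((2, 1, 4, 4)) for _ in range(4))
        alpha = 0.7
        expected = (np.mean((r1 - 1) ** 2) + np.mean(f1 ** 2)
                    + alpha * (np.mean((r2 - 1) ** 2) + np.mean(f2 ** 2)))
        assert adversarial_loss(r1, f1, r2, f2, alpha) == pytest.approx(expected)

    def test_nonfinite_scores_rejected(self):
        with pytest.raises(ValueError):
            adversarial_loss(np.nan, 0.0, 1.0, 0.0, 1.0)


class TestCycleLoss:
    def test_identical_images_zero(self, rng):
        img = rng.random((8, 8))
        assert cycle_loss(img, img) == 0.0

    def test_constants(self):
        a = np.full((4, 4), 0.2)
        b = np.full((4, 4), 0.9)
        assert cycle_loss(a, b) == pytest.approx(0.7)

    def test_matches_direct_summation(self, rng):
        a, b = rng.random((10, 10)), rng.random((10, 10))
        expected = sum(abs(a[i, j] - b[i, j]) for i in range(10)
                       for j in range(10)) / 100
        assert cycle_loss(a, b) == pytest.approx(expected, abs=1e-12)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            cycle_loss(rng.random((4, 4)), rng.random((5, 5)))


class TestNetworks:
    def test_generator_preserves_shape_and_range(self, rng):
        gen = build_generator(seed=0)
        x = rng.uniform(-1, 1, (1, 1, 32, 32))
        y = gen.forward(x, train=False)
        assert y.shape == x.shape
        assert y.min() >= -1.0 and y.max() <= 1.0

    def test_generator_seeded_init_identical(self):
        a = build_generator(seed=4)
        b = build_generator(seed=4)
        for pa, pb in zip(a.params(), b.params()):
            np.testing.assert_array_equal(pa.data, pb.data)

    def test_discriminator_returns_two_heads_batched(self, rng):
        disc = build_discriminator(seed=1)
        x = rng.uniform(-1, 1, (3, 1, 32, 32))
        d1, d2 = disc.forward(x, train=False)
        assert d1.shape[0] == 3 and d2.shape[0] == 3
        assert d1.shape == d2.shape

    def test_discriminator_seeded_init_identical(self, rng):
        x = rng.uniform(-1, 1, (1, 1, 32, 32))
        d1a, d2a = build_discriminator(seed=2).forward(x, train=False)
        d1b, d2b = build_discriminator(seed=2).forward(x, train=False)
        np.testing.assert_array_equal(d1a, d1b)
        np.testing.assert_array_equal(d2a, d2b)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            GeneratorSpec(n_layers=6)


class TestGradients:
    def test_conv_bn_chain_gradient_matches_finite_differences(self):
        """Backprop through Conv-BN-ReLU agrees with numeric differentiation."""
        from cyclereg import nn
        rng = np.random.default_rng(0)
        net = nn.Sequential([nn.Conv2d(1, 2, 3, 1, rng), nn.BatchNorm2d(2),
                             nn.ReLU(), nn.Conv2d(2, 1, 3, 2, rng)])
        x = rng.standard_normal((2, 1, 8, 8))
        y = net.forward(x, train=True)
        loss_grad = np.ones_like(y) / y.size
        net.backward(loss_grad)
        p = net.params()[0]
        analytic = p.grad.ravel()[3]
        eps = 1e-6
        for sign in (+1, -1):
            p.data.ravel()[3] += sign * eps
            val = net.forward(x, train=True).mean()
            net.clear_cache()
            p.data.ravel()[3] -= sign * eps
            if sign > 0:
                up = val
            else:
                down = val
        assert analytic == pytest.approx((up - down) / (2 * eps), rel=1e-4)


@pytest.fixture(scope="module")
def tiny_patches():
    from cyclereg import PhantomParams, make_paired_case
    p = PhantomParams(image_size=96, seed=50)
    case = make_paired_case(p)
    ct = extract_patches(case.image_ct, 32, 16, seed=1)
    tee = extract_patches(case.image_tee, 32, 16, seed=2)
    return ct, tee


class TestTraining:
    def test_zero_iterations_returns_initial_model(self, tiny_patches):
        ct, tee = tiny_patches
        cfg = TrainConfig(max_iterations=0, seed=3)
        model = train_cyclegan(ct, tee, cfg)
        ref = TranslationModel.initialize(cfg)
        for pa, pb in zip(model.G_ct2tee.params(), ref.G_ct2tee.params()):
            np.testing.assert_array_equal(pa.data, pb.data)
        assert model.iteration == 0

    def test_seeded_determinism_of_loss_history(self, tiny_patches):
        ct, tee = tiny_patches
        cfg = TrainConfig(max_iterations=4, seed=9)
        h1 = train_cyclegan(ct, tee, cfg).loss_history
        h2 = train_cyclegan(ct, tee, cfg).loss_history
        assert h1 == h2

    def test_empty_patchset_rejected(self, tiny_patches):
        from cyclereg.io import PatchSet
        with pytest.raises(ValueError):
            train_cyclegan(PatchSet(), tiny_patches[1], TrainConfig())

    def test_checkpoint_round_trip_bit_identical(self, tiny_patches, tmp_path,
                                                 rng):
        ct, tee = tiny_patches
        model = train_cyclegan(ct, tee, TrainConfig(max_iterations=3, seed=1))
        img = ImageGrid(rng.uniform(-1, 1, (32, 32)))
        before = translate(model, img, "ct2tee").pixels
        save_model(model, str(tmp_path / "ckpt"))
        loaded = load_model(str(tmp_path / "ckpt"))
        after = translate(loaded, img, "ct2tee").pixels
        np.testing.assert_array_equal(before, after)
        assert loaded.iteration == model.iteration


class TestTrainingImprovesCycle:
    def test_trained_model_reconstructs_better_than_untrained(self,
                                                              tiny_patches):
        """After a short run, ct2tee followed by tee2ct reconstructs the
        original image better than the iteration-0 model does."""
        from cyclereg import cycle_loss
        ct, tee = tiny_patches
        cfg = TrainConfig(max_iterations=60, seed=21)
        trained = train_cyclegan(ct, tee, cfg)
        untrained = TranslationModel.initialize(cfg)
        img = ImageGrid(ct.patches[0].pixels * 2.0 - 1.0)

        def round_trip(model):
            fwd = translate(model, img, "ct2tee")
            back = translate(model, fwd, "tee2ct")
            return cycle_loss(img.pixels, back.pixels)

        assert round_trip(trained) < round_trip(untrained)


class TestTranslate:
    def test_output_shape_and_tag(self, tiny_patches, rng):
        ct, tee = tiny_patches
        model = TranslationModel.initialize(TrainConfig(seed=0))
        img = ImageGrid(rng.uniform(-1, 1, (48, 37)))
        out = translate(model, img, "ct2tee")
        assert out.shape == img.shape
        assert out.modality == "TEE_LIKE"
        assert translate(model, img, "tee2ct").modality == "CT_LIKE"

    def test_repeated_calls_bit_identical(self, rng):
        model = TranslationModel.initialize(TrainConfig(seed=0))
        img = ImageGrid(rng.uniform(-1, 1, (32, 32)))
        a = translate(model, img, "ct2tee").pixels
        b = translate(model, img, "ct2tee").pixels
        np.testing.assert_array_equal(a, b)

    def test_unnormalized_input_rejected(self, rng):
        model = TranslationModel.initialize(TrainConfig(seed=0))
        img = ImageGrid(rng.uniform(0, 255, (32, 32)))
        with pytest.raises(ValueError):
            translate(model, img, "ct2tee")

    def test_normalized_phantom_accepted(self, small_case):
        model = TranslationModel.initialize(TrainConfig(seed=0))
        img = normalize_intensity(small_case.image_ct, "symmetric")
        out = translate(model, img, "ct2tee")
        assert np.all(np.abs(out.pixels) <= 1.0)
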