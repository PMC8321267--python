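"""Architecture contracts, loss arithmetic and training behaviour of
the two-domain adversarial translator."""

import dataclasses

import numpy as np
import pytest

from derm2macro import translation
from derm2macro.nn import Tensor
from derm2macro.translation import (CycleGANConfig, DiscriminatorSpec,
                                    GeneratorSpec, adversarial_loss,
                                    build_discriminator, build_generator,
                                    cycle_loss, total_loss, train_cyclegan,
                                    translate)

SMOKE_GEN = GeneratorSpec(input_size=32, base_channels=4, n_residual_blocks=2)
SMOKE_DISC = DiscriminatorSpec(base_channels=4)


def _batch(rng, size=32, n=1):
    return Tensor(rng.uniform(-1, 1, size=(n, 3, size, size)))


def _gan_samples(dataset):
    return [dataclasses.replace(s, pixels=s.pixels * 2 - 1) for s in dataset]


class TestGenerator:
    def test_forward_preserves_shape_with_tanh_range(self, rng):
        gen = build_generator(GeneratorSpec(input_size=64, base_channels=4,
                                            n_residual_blocks=12))
        y = gen(_batch(rng, 64, 2))
        assert y.shape == (2, 3, 64, 64)
        assert y.data.min() >= -1.0 and y.data.max() <= 1.0

    @pytest.mark.parametrize("n_blocks", [9, 12])
    def test_residual_block_count_is_configurable(self, n_blocks):
        gen = build_generator(GeneratorSpec(input_size=32, base_channels=4,
                                            n_residual_blocks=n_blocks))
        assert gen.n_residual_blocks == n_blocks

    def test_zeroed_head_gives_zero_output(self, rng):
        gen = build_generator(SMOKE_GEN)
        gen.head.weight.data[:] = 0
        gen.head.bias.data[:] = 0
        y = gen(_batch(rng))
        assert np.allclose(y.data, 0.0)  # tanh(0) = 0

    def test_indivisible_input_size_rejected(self):
        with pytest.raises(ValueError):
            GeneratorSpec(input_size=34)


class TestDiscriminator:
    def test_patch_map_side_is_input_over_32(self, rng):
        disc = build_discriminator(SMOKE_DISC)
        assert disc(_batch(rng, 64)).shape == (1, 1, 2, 2)
        assert disc(_batch(rng, 128)).shape == (1, 1, 4, 4)

    def test_outputs_are_probabilities(self, rng):
        disc = build_discriminator(SMOKE_DISC)
        p = disc(_batch(rng, 64)).data
        assert np.all(p > 0) and np.all(p < 1)

    def test_input_below_receptive_stride_rejected(self, rng):
        disc = build_discriminator(SMOKE_DISC)
        with pytest.raises(ValueError):
            disc(_batch(rng, 16))


class TestLosses:
    def test_half_probabilities_give_ln_two(self):
        probs = np.full((1, 1, 2, 2), 0.5)
        assert adversarial_loss(probs, "ones").item() == \
            pytest.approx(np.log(2), abs=1e-9)

    def test_confident_real_tends_to_zero(self):
        probs = np.full((1, 1, 2, 2), 1 - 1e-9)
        assert adversarial_loss(probs, "ones").item() < 1e-6

    def test_mixed_patch_matches_hand_computation(self):
        vals = np.array([0.9, 0.8, 0.6, 0.7])
        probs = vals.reshape(1, 1, 2, 2)
        expected = float(np.mean(-np.log(vals)))
        assert adversarial_loss(probs, "ones").item() == \
            pytest.approx(expected, abs=1e-12)
        expected_zeros = float(np.mean(-np.log(1 - vals)))
        assert adversarial_loss(probs, "zeros").item() == \
            pytest.approx(expected_zeros, abs=1e-12)

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValueError):
            adversarial_loss(np.array([1.2]), "ones")
        with pytest.raises(ValueError):
            adversarial_loss(np.array([0.5]), "maybe")

    def test_perfect_reconstruction_gives_zero_cycle_loss(self, rng):
        x = rng.uniform(-1, 1, size=(1, 3, 8, 8))
        y = rng.uniform(-1, 1, size=(1, 3, 8, 8))
        assert cycle_loss(x, x, y, y).item() == 0.0

    def test_constant_offset_one_direction(self, rng):
        x = rng.uniform(-1, 1, size=(1, 3, 8, 8))
        y = rng.uniform(-0.5, 0.5, size=(1, 3, 8, 8))
        assert cycle_loss(x, x + 0.1, y, y).item() == pytest.approx(0.1)

    def test_cycle_loss_matches_elementwise_oracle(self, rng):
        x, xr, y, yr = (rng.uniform(-1, 1, size=(2, 3, 4, 4))
                        for _ in range(4))
        expected = np.abs(x - xr).mean() + np.abs(y - yr).mean()
        assert cycle_loss(x, xr, y, yr).item() == pytest.approx(expected)

    def test_total_loss_arithmetic(self):
        assert total_loss(0.5, 0.7, 0.2, 10) == pytest.approx(3.2)
        assert total_loss(0.5, 0.7, 0.0, 10) == pytest.approx(1.2)
        assert CycleGANConfig().lambda_cyc == 10.0


@pytest.fixture(scope="module")
def smoke_bundle(small_two_domain):
    macro, dermo = small_two_domain
    cfg = CycleGANConfig(generator=SMOKE_GEN, discriminator=SMOKE_DISC,
                         max_epochs=3, seed=0)
    return train_cyclegan(_gan_samples(dermo), _gan_samples(macro), cfg), \
        macro, dermo


class TestTraining:
    def test_history_contract(self, smoke_bundle):
        bundle, _, _ = smoke_bundle
        assert len(bundle.history) <= 3
        assert np.isfinite(bundle.history.drop(columns="epoch").to_numpy()).all()
        cols = set(bundle.history.columns)
        assert {"loss_G_total", "loss_cyc", "loss_D_X", "loss_D_Y"} <= cols

    def test_loss_decomposition_in_history(self, smoke_bundle):
        bundle, _, _ = smoke_bundle
        h = bundle.history
        recomposed = h.loss_gan_F + h.loss_gan_G + 10.0 * h.loss_cyc
        assert np.allclose(recomposed, h.loss_G_total)

    def test_training_is_deterministic_under_seed(self, small_two_domain):
        macro, dermo = small_two_domain
        cfg = CycleGANConfig(generator=SMOKE_GEN, discriminator=SMOKE_DISC,
                             max_epochs=2, seed=7)
        h1 = train_cyclegan(_gan_samples(dermo), _gan_samples(macro),
                            cfg).history
        h2 = train_cyclegan(_gan_samples(dermo), _gan_samples(macro),
                            cfg).history
        assert h1.equals(h2)

    def test_empty_dataset_rejected(self, small_two_domain):
        macro, _ = small_two_domain
        cfg = CycleGANConfig(generator=SMOKE_GEN, discriminator=SMOKE_DISC,
                             max_epochs=1)
        with pytest.raises(ValueError):
            train_cyclegan([], _gan_samples(macro), cfg)

    def test_cycle_loss_decreases_on_separated_domains(self, small_two_domain):
        macro, dermo = small_two_domain
        cfg = CycleGANConfig(generator=SMOKE_GEN, discriminator=SMOKE_DISC,
                             max_epochs=8, seed=1)
        hist = train_cyclegan(_gan_samples(dermo), _gan_samples(macro),
                              cfg).history
        assert hist.loss_cyc.iloc[-1] < hist.loss_cyc.iloc[0]


class TestTranslate:
    def test_counts_tags_and_masks(self, smoke_bundle):
        bundle, _, dermo = smoke_bundle
        out = translate(bundle, _gan_samples(dermo), "dermo_to_macro")
        assert len(out) == len(dermo)
        for orig, t in zip(dermo, out):
            assert t.domain == "trans_macro"
            assert t.pixels.shape == orig.pixels.shape
            assert np.array_equal(t.mask, orig.mask)

    def test_macro_to_dermo_tags(self, smoke_bundle):
        bundle, macro, _ = smoke_bundle
        out = translate(bundle, _gan_samples(macro), "macro_to_dermo")
        assert all(s.domain == "trans_dermo" for s in out)

    def test_round_trip_l1_equals_cycle_term(self, smoke_bundle):
        bundle, _, dermo = smoke_bundle
        samples = _gan_samples(dermo)[:3]
        forward = translate(bundle, samples, "dermo_to_macro")
        back = translate(bundle, forward, "macro_to_dermo")
        l1 = np.mean([np.abs(a.pixels - b.pixels).mean()
                      for a, b in zip(samples, back)])
        # same quantity via the loss function on the stacked batch
        x = np.stack([s.pixels.transpose(2, 0, 1) for s in samples])
        xr = np.stack([s.pixels.transpose(2, 0, 1) for s in back])
        via_loss = cycle_loss(x, xr, x, xr).item() / 2
        assert np.isfinite(l1)
        assert l1 == pytest.approx(via_loss, rel=1e-12)

    def test_size_mismatch_rejected(self, smoke_bundle, rng):
        bundle, _, _ = smoke_bundle
        from derm2macro.preprocessing import ImageSample
        bad = ImageSample(pixels=rng.uniform(-1, 1, (64, 64, 3)),
                          domain="dermo", id="bad")
        with pytest.raises(ValueError):
            translate(bundle, [bad], "dermo_to_macro")

    def test_unknown_direction_rejected(self, smoke_bundle):
        bundle, macro, _ = smoke_bundle
        with pytest.raises(ValueError):
            translate(bundle, _gan_samples(macro), "sideways")


def test_bundle_checkpoint_roundtrip(tmp_path, smoke_bundle):
    bundle, _, dermo = smoke_bundle
    path = translation.save_bundle(bundle, tmp_path / "ck.zip")
    loaded = translation.load_bundle(path)
    samples = _gan_samples(dermo)[:2]
    a = translate(bundle, samples, "dermo_to_macro")
    b = translate(loaded, samples, "dermo_to_macro")
    for s1, s2 in zip(a, b):
        assert np.array_equal(s1.pixels, s2.pixels)
    assert loaded.config == bundle.config
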