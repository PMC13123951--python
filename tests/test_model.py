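import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from usgan.model import (ACG, BACKWARD, FORWARD, Discriminator, Generator,
                         ModelBundle, adain)

RNG = np.random.default_rng(77)


class TestAdain:
    def test_hand_arithmetic_single_channel(self):
        # population sigma of [1,2,3] is sqrt(2/3); shift 0 / scale 1
        out = adain(np.array([[[1.0, 2.0, 3.0]]]), np.array([0.0]), np.array([1.0]))
        np.testing.assert_allclose(out.ravel(), [-1.22474487, 0.0, 1.22474487],
                                   atol=1e-4)

    def test_identity_renormalization(self):
        f = RNG.uniform(-1, 1, (2, 4, 4))
        mu = f.mean(axis=(1, 2))
        sigma = f.std(axis=(1, 2))
        out = adain(f, shift=mu, scale=sigma)
        np.testing.assert_allclose(out, f, atol=1e-3)

    def test_constant_channel_maps_to_target_mean(self):
        f = np.full((1, 3, 3), 0.7)
        out = adain(f, np.array([0.2]), np.array([3.0]))
        np.testing.assert_allclose(out, 0.2, atol=1e-6)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(hnp.arrays(np.float64, (2, 5, 5),
                      elements=st.floats(-3, 3, allow_nan=False)),
           st.floats(-2, 2), st.floats(0.1, 3))
    def test_output_statistics_equal_code_for_nonconstant_channels(
            self, f, shift, scale):
        assume(all(f[c].std() > 0.05 for c in range(2)))
        eps = 1e-5
        out = adain(f, np.full(2, shift), np.full(2, scale), eps=eps)
        for c in range(2):
            assert abs(out[c].mean() - shift) < 10 * eps
            assert abs(out[c].std() - scale) < 10 * eps * (1 + scale)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="channels"):
            adain(np.zeros((2, 3, 3)), np.zeros(3), np.ones(3))


class TestACG:
    def test_directions_give_different_codes(self):
        acg = ACG(n_layers=4, channels=8, rng=np.random.default_rng(3))
        cf = acg.forward(FORWARD)
        cb = acg.forward(BACKWARD)
        diffs = [np.abs(a - b).max() for a, b in zip(cf.shifts, cb.shifts)]
        diffs += [np.abs(a - b).max() for a, b in zip(cf.scales, cb.scales)]
        assert max(diffs) > 0

    def test_deterministic_and_positive_scales(self):
        acg = ACG(n_layers=2, channels=4, rng=np.random.default_rng(5))
        a = acg.forward(FORWARD)
        b = acg.forward(FORWARD)
        for s1, s2 in zip(a.shifts, b.shifts):
            assert np.array_equal(s1, s2)
        for sc in a.scales:
            assert np.all(sc > 0)

    def test_unknown_tag_rejected(self):
        acg = ACG(2, 4)
        with pytest.raises(ValueError, match="direction"):
            acg.forward("sideways")


class TestGenerator:
    def test_256_input_gives_256_output_feed_forward(self):
        bundle = ModelBundle.create(base_channels=8, n_res_blocks=2, seed=0)
        img = RNG.uniform(0, 1, (256, 256))
        out = bundle.generate(img, FORWARD)
        assert out.shape == (256, 256)
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_feed_forward_determinism(self):
        bundle = ModelBundle.create(base_channels=8, n_res_blocks=2, seed=1)
        img = RNG.uniform(0, 1, (64, 64))
        a = bundle.generate(img, FORWARD)
        b = bundle.generate(img, FORWARD)
        assert np.array_equal(a, b)

    def test_indivisible_size_names_required_multiple(self):
        bundle = ModelBundle.create(base_channels=8, n_res_blocks=1, seed=0)
        with pytest.raises(ValueError, match="multiples of 4"):
            bundle.generate(RNG.uniform(0, 1, (66, 66)), FORWARD)

    def test_direction_switch_changes_output(self):
        bundle = ModelBundle.create(base_channels=8, n_res_blocks=2, seed=2)
        img = RNG.uniform(0, 1, (64, 64))
        fwd = bundle.generate(img, FORWARD)
        bwd = bundle.generate(img, BACKWARD)
        assert not np.array_equal(fwd, bwd)

    def test_parameter_gradients_finite_and_not_all_zero(self):
        """Finite-difference spot check on parameters from three layers."""
        bundle = ModelBundle.create(base_channels=8, n_res_blocks=2, seed=3,
                                    dtype=np.float64)
        gen, acg = bundle.generator, bundle.acg
        x = np.random.default_rng(0).uniform(0.2, 0.8, (1, 1, 16, 16))
        w = np.random.default_rng(1).standard_normal((1, 1, 16, 16))

        def loss():
            code = acg.forward(FORWARD)
            y, _ = gen.forward(2 * x - 1, code)
            return float((y * w).sum())

        code, cache_a = acg.forward(FORWARD, with_cache=True)
        y, caches = gen.forward(2 * x - 1, code)
        gen.zero_grad()
        acg.zero_grad()
        _, dsh, dsc = gen.backward(w, caches)
        acg.backward(dsh, dsc, cache_a)

        checks = [(gen.layers[0], "W", (0, 0, 3, 3)),
                  (gen.layers[4], "W", (1, 0, 1, 1)),
                  (acg.fc1, "W", (2, 0))]
        eps = 1e-6
        for ly, key, idx in checks:
            assert np.all(np.isfinite(ly.g[key]))
            assert np.abs(ly.g[key]).max() > 0
            orig = ly.p[key][idx]
            ly.p[key][idx] = orig + eps
            fp = loss()
            ly.p[key][idx] = orig - eps
            fm = loss()
            ly.p[key][idx] = orig
            num = (fp - fm) / (2 * eps)
            assert abs(ly.g[key][idx] - num) < 1e-4 * max(1.0, abs(num))


class TestDiscriminator:
    def test_score_grid_shape_from_four_stride2_blocks(self):
        disc = Discriminator(base_channels=4, n_blocks=4,
                             rng=np.random.default_rng(0))
        scores, _ = disc.forward(RNG.uniform(0, 1, (1, 1, 256, 256)))
        assert scores.shape == (1, 1, 16, 16)

    def test_deterministic(self):
        disc = Discriminator(base_channels=4, rng=np.random.default_rng(0))
        img = RNG.uniform(0, 1, (64, 64))
        assert np.array_equal(disc.score(img), disc.score(img))

    def test_a_and_b_are_independent(self):
        bundle = ModelBundle.create(base_channels=8, n_res_blocks=1, seed=4)
        img = RNG.uniform(0, 1, (64, 64))
        before = bundle.discriminate(img, "B")
        for layer in bundle.disc_a.layers:
            for k in layer.p:
                layer.p[k] = layer.p[k] + 0.1
        after = bundle.discriminate(img, "B")
        assert np.array_equal(before, after)
        with pytest.raises(ValueError):
            bundle.discriminate(img, "C")


class TestCheckpoint:
    def test_round_trip_reproduces_outputs_bit_identically(self, tmp_path):
        bundle = ModelBundle.create(base_channels=8, n_res_blocks=2, seed=9)
        img = np.random.default_rng(5).uniform(0, 1, (64, 64))
        out_before = bundle.generate(img, FORWARD)
        path = tmp_path / "ckpt.npz"
        bundle.save(path)
        loaded = ModelBundle.load(path)
        out_after = loaded.generate(img, FORWARD)
        assert np.array_equal(out_before, out_after)
        assert np.array_equal(bundle.discriminate(img, "A"),
                              loaded.discriminate(img, "A"))

    def test_shared_generator_contract(self):
        """Forward and backward translations use the same generator weights."""
        bundle = ModelBundle.create(base_channels=8, n_res_blocks=1, seed=0)
        img = np.random.default_rng(2).uniform(0, 1, (32, 32))
        params_before = [ly.p[k].copy() for ly in bundle.generator.layers
                         for k in ly.p]
        bundle.generate(img, FORWARD)
        bundle.generate(img, BACKWARD)
        params_after = [ly.p[k] for ly in bundle.generator.layers for k in ly.p]
        for a, b in zip(params_before, params_after):
            assert np.array_equal(a, b)
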