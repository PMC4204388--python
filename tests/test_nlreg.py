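"""Non-local regularizer: brute-force oracle equivalence and weight properties."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from nchr import nlreg
from nchr.nlreg import PatchConfig


def _random_pair(rng, shape, noise=0.6):
    cur = rng.random(shape)
    noisy = cur + noise * rng.standard_normal(shape)
    return cur, noisy


class TestExtractPatch:
    def test_constant_image_gives_constant_patch(self, small_cfg):
        img = np.full((7, 7), 3.5)
        patch = nlreg.extract_patch(img, (0, 6), small_cfg)
        assert patch.shape == (3, 3)
        assert np.all(patch == 3.5)

    def test_interior_extraction_is_verbatim(self, small_cfg):
        img = np.arange(25, dtype=float).reshape(5, 5)
        patch = nlreg.extract_patch(img, (2, 2), small_cfg)
        np.testing.assert_array_equal(patch, img[1:4, 1:4])

    def test_corner_patch_is_reflection_symmetric(self, small_cfg):
        rng = np.random.default_rng(0)
        img = rng.random((6, 6))
        patch = nlreg.extract_patch(img, (0, 0), small_cfg)
        # symmetric padding mirrors the first row/column about the corner
        assert patch[0, 1] == patch[1, 1] == img[0, 0]
        assert patch[1, 0] == img[0, 0]
        assert patch[2, 2] == img[1, 1]

    def test_out_of_bounds_center_raises(self, small_cfg):
        with pytest.raises(IndexError):
            nlreg.extract_patch(np.zeros((4, 4)), (4, 0), small_cfg)


class TestAlphaAndShrinkage:
    def test_alpha_excludes_self_and_is_symmetric(self):
        assert nlreg.alpha((5, 5), (5, 5)) == 0
        assert nlreg.alpha((3, 7), (3, 8)) == 1
        for x, i in [((0, 0), (1, 0)), ((2, 3), (3, 2))]:
            assert nlreg.alpha(x, i) == nlreg.alpha(i, x)

    @pytest.mark.parametrize(
        "rsq, sigma, n, expected",
        [
            (100.0, 0.3, 441, 1.0 - 439 * 0.09 / 100.0),  # = 0.6049
            (1.0, 0.3, 441, 0.0),  # residual below the shrinkage threshold
            (5.0, 0.0, 441, 1.0),  # no shrinkage at zero sigma
            (0.0, 0.5, 9, 0.0),  # zero residual -> fully gated
        ],
    )
    def test_closed_form_values(self, rsq, sigma, n, expected):
        assert nlreg.js_shrinkage_factor(rsq, sigma, n) == pytest.approx(expected)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            nlreg.js_shrinkage_factor(-1.0, 0.3, 9)
        with pytest.raises(ValueError):
            nlreg.js_shrinkage_factor(1.0, 0.3, 2)


class TestWeightsAgainstOracle:
    @pytest.mark.parametrize("mode", ["js", "conventional"])
    @pytest.mark.parametrize("shape", [(8, 8), (16, 16), (10, 13)])
    def test_field_matches_nested_loops(self, rng, small_cfg, mode, shape):
        cur, noisy = _random_pair(rng, shape)
        field = nlreg.compute_weights(
            cur, 0.5, small_cfg, noisy_image=noisy, mode=mode
        )
        brute = oracles.weight_field(cur, noisy, 0.5, 3, 5, mode=mode)
        np.testing.assert_allclose(field.weights, brute, rtol=1e-10, atol=1e-14)

    def test_neighborhood_count_variant_matches_oracle(self, rng, small_cfg):
        cur, noisy = _random_pair(rng, (8, 8), noise=1.5)
        field = nlreg.compute_weights(
            cur, 0.3, small_cfg, noisy_image=noisy, mode="js", js_norm="neighborhood"
        )
        brute = oracles.weight_field(cur, noisy, 0.3, 3, 5, js_norm="neighborhood")
        np.testing.assert_allclose(field.weights, brute, rtol=1e-10, atol=1e-14)

    def test_scalar_ops_agree_with_field(self, rng, small_cfg):
        cur, noisy = _random_pair(rng, (9, 9))
        field = nlreg.compute_weights(cur, 0.5, small_cfg, noisy_image=noisy)
        conv_field = nlreg.compute_weights(cur, 0.5, small_cfg, mode="conventional")
        for x in [(3, 3), (4, 6), (2, 2)]:
            for off in [(-2, 1), (0, 2), (1, -1)]:
                i = (x[0] + off[0], x[1] + off[1])
                assert 0 <= i[0] < 9 and 0 <= i[1] < 9
                assert nlreg.nl_weight(cur, x, i, 0.5, noisy, small_cfg) == pytest.approx(
                    field.weights[off[0] + 2, off[1] + 2, x[0], x[1]], rel=1e-12
                )
                assert nlreg.conventional_nl_weight(
                    cur, x, i, 0.5, small_cfg
                ) == pytest.approx(
                    conv_field.weights[off[0] + 2, off[1] + 2, x[0], x[1]], rel=1e-12
                )

    def test_self_weight_is_zero(self, rng, small_cfg):
        cur, noisy = _random_pair(rng, (6, 6))
        assert nlreg.nl_weight(cur, (3, 3), (3, 3), 0.4, noisy, small_cfg) == 0.0
        assert nlreg.conventional_nl_weight(cur, (3, 3), (3, 3), 0.4, small_cfg) == 0.0
        field = nlreg.compute_weights(cur, 0.4, small_cfg, noisy_image=noisy)
        assert np.all(field.weights[2, 2] == 0.0)

    def test_zero_residual_gates_modified_weight_off(self, rng, small_cfg):
        cur = rng.random((6, 6))
        # noisy == current estimate: no residual evidence, all weights vanish
        assert nlreg.nl_weight(cur, (2, 2), (2, 3), 0.4, cur, small_cfg) == 0.0
        field = nlreg.compute_weights(cur, 0.4, small_cfg, noisy_image=cur)
        assert field.is_zero and not field.weights.any()

    def test_identical_patches_give_unit_conventional_weight(self, small_cfg):
        img = np.full((8, 8), 0.7)
        assert nlreg.conventional_nl_weight(img, (3, 3), (3, 5), 0.5, small_cfg) == 1.0

    def test_sigma_must_be_positive(self, rng, small_cfg):
        cur, noisy = _random_pair(rng, (6, 6))
        with pytest.raises(ValueError):
            nlreg.nl_weight(cur, (2, 2), (2, 3), 0.0, noisy, small_cfg)
        with pytest.raises(ValueError):
            nlreg.compute_weights(cur, -0.1, small_cfg, noisy_image=noisy)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), sigma=st.floats(0.05, 2.0))
    def test_modified_bounded_by_conventional_bounded_by_one(self, seed, sigma):
        rng = np.random.default_rng(seed)
        cfg = PatchConfig(patch_size=3, neighborhood_size=5)
        cur, noisy = _random_pair(rng, (8, 8))
        js = nlreg.compute_weights(cur, sigma, cfg, noisy_image=noisy, mode="js")
        conv = nlreg.compute_weights(cur, sigma, cfg, mode="conventional")
        assert np.all(js.weights >= 0.0)
        assert np.all(js.weights <= conv.weights + 1e-15)
        assert np.all(conv.weights <= 1.0 + 1e-15)

    def test_conventional_weights_are_symmetric_in_pair_swap(self, rng, small_cfg):
        """w(x, i) == w(i, x) without the shrinkage factor (the modified
        weights carry an x-only factor and are deliberately not symmetric)."""
        cur = rng.random((8, 8))
        field = nlreg.compute_weights(cur, 0.5, small_cfg, mode="conventional")
        Rn = 2
        for y in range(2, 6):
            for x in range(2, 6):
                for dy, dx in [(1, 0), (0, 2), (-1, 1), (2, -2)]:
                    w_xi = field.weights[dy + Rn, dx + Rn, y, x]
                    w_ix = field.weights[-dy + Rn, -dx + Rn, y + dy, x + dx]
                    assert w_xi == pytest.approx(w_ix, rel=1e-12)


class TestRhoAndGradient:
    def test_rho_zero_on_constant_image_and_zero_weights(self, rng, small_cfg):
        cur, noisy = _random_pair(rng, (8, 8))
        field = nlreg.compute_weights(cur, 0.5, small_cfg, noisy_image=noisy)
        assert nlreg.rho(np.full((8, 8), 2.0), 0.5, field, small_cfg) == 0.0
        zero_field = nlreg.compute_weights(cur, 0.5, small_cfg, noisy_image=cur)
        assert nlreg.rho(rng.random((8, 8)), 0.5, zero_field, small_cfg) == 0.0

    @pytest.mark.parametrize("mode", ["js", "conventional"])
    def test_rho_matches_brute_force(self, rng, small_cfg, mode):
        cur, noisy = _random_pair(rng, (8, 8))
        img = rng.random((8, 8))
        field = nlreg.compute_weights(cur, 0.5, small_cfg, noisy_image=noisy, mode=mode)
        brute = oracles.rho(img, field.weights, 3, 5)
        assert nlreg.rho(img, 0.5, field, small_cfg) == pytest.approx(brute, rel=1e-10)

    def test_gradient_matches_brute_force_accumulation(self, rng, small_cfg):
        cur, noisy = _random_pair(rng, (8, 8))
        img = rng.random((8, 8))
        field = nlreg.compute_weights(cur, 0.5, small_cfg, noisy_image=noisy)
        g = nlreg.rho_gradient(img, 0.5, field, small_cfg)
        brute = oracles.rho_gradient(img, field.weights, 3, 5)
        np.testing.assert_allclose(g, brute, rtol=1e-9, atol=1e-12)

    def test_gradient_matches_central_finite_differences(self, rng, small_cfg):
        cur, noisy = _random_pair(rng, (8, 8))
        img = rng.random((8, 8))
        field = nlreg.compute_weights(cur, 0.5, small_cfg, noisy_image=noisy)
        g = nlreg.rho_gradient(img, 0.5, field, small_cfg)
        h = 1e-5
        fd = np.zeros_like(img)
        for y in range(8):
            for x in range(8):
                plus, minus = img.copy(), img.copy()
                plus[y, x] += h
                minus[y, x] -= h
                fd[y, x] = (
                    nlreg.rho(plus, 0.5, field, small_cfg)
                    - nlreg.rho(minus, 0.5, field, small_cfg)
                ) / (2 * h)
        np.testing.assert_allclose(g, fd, rtol=1e-4, atol=1e-6)

    def test_gradient_zero_on_constant_image(self, rng, small_cfg):
        cur, noisy = _random_pair(rng, (8, 8))
        field = nlreg.compute_weights(cur, 0.5, small_cfg, noisy_image=noisy)
        g = nlreg.rho_gradient(np.full((8, 8), 1.3), 0.5, field, small_cfg)
        np.testing.assert_allclose(g, 0.0, atol=1e-12)

    def test_gradient_is_linear_in_image_under_frozen_weights(self, rng, small_cfg):
        cur, noisy = _random_pair(rng, (8, 8))
        img = rng.random((8, 8))
        field = nlreg.compute_weights(cur, 0.5, small_cfg, noisy_image=noisy)
        g1 = nlreg.rho_gradient(img, 0.5, field, small_cfg)
        g3 = nlreg.rho_gradient(3.0 * img, 0.5, field, small_cfg)
        np.testing.assert_allclose(g3, 3.0 * g1, rtol=1e-10)

    def test_rho_decreases_along_small_gradient_step(self, rng, small_cfg):
        cur, noisy = _random_pair(rng, (10, 10))
        img = rng.random((10, 10))
        field = nlreg.compute_weights(cur, 0.5, small_cfg, noisy_image=noisy)
        g = nlreg.rho_gradient(img, 0.5, field, small_cfg)
        before = nlreg.rho(img, 0.5, field, small_cfg)
        after = nlreg.rho(img - 1e-6 * g, 0.5, field, small_cfg)
        assert after <= before


class TestPatchConfigValidation:
    @pytest.mark.parametrize("ps, ns", [(4, 21), (9, 20), (11, 9), (0, 5)])
    def test_bad_geometry_rejected(self, ps, ns):
        with pytest.raises(ValueError):
            PatchConfig(patch_size=ps, neighborhood_size=ns)

    def test_defaults_match_operating_point(self):
        cfg = PatchConfig()
        assert (cfg.patch_size, cfg.neighborhood_size) == (9, 21)
        assert cfg.n_patch_px == 81 and cfg.n_neigh_px == 441
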