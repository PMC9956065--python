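"""The synthetic-pair generator: deformation sampling under caps, TPS
interpolation, intensity augmentation, and phantom construction."""

import os

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.interpolate import RBFInterpolator

from oracles import invert_field_oracle, tps_dense_oracle
from voxreg.losses import global_ncc
from voxreg.synthesis import (AugmentationConfig, EvalPair, cap_field,
                              control_grid_points, desk_augmentation,
                              generate_pair, generate_phantom,
                              intensity_augment, make_eval_pairs,
                              sample_intensity_params, sample_nonrigid,
                              sample_rigid, tps_fit)
from voxreg.volumes import DisplacementField, Volume
from voxreg.warp import warp_volume


def identity_config() -> AugmentationConfig:
    return AugmentationConfig(
        gamma_range=(1.0, 1.0), brightness_frac=0.0, max_rotation_deg=0.0,
        max_rigid_translation_mm=0.0, max_nonrigid_disp_mm=0.0,
        control_grid=(3, 3, 3),
    )


class TestConfig:
    def test_defaults_match_protocol(self):
        cfg = AugmentationConfig()
        assert cfg.gamma_range == (0.5, 2.0)
        assert cfg.brightness_frac == 0.20
        assert cfg.max_rotation_deg == 10.0
        assert cfg.max_rigid_translation_mm == 30.0
        assert cfg.max_nonrigid_disp_mm == 6.0
        assert cfg.control_grid == (8, 8, 8)

    def test_invalid_ranges_rejected(self):
        with pytest.raises(ValueError):
            AugmentationConfig(gamma_range=(2.0, 0.5))
        with pytest.raises(ValueError):
            AugmentationConfig(max_rotation_deg=-1)
        with pytest.raises(ValueError):
            AugmentationConfig(control_grid=(1, 8, 8))


class TestSampleRigid:
    def test_caps_hold_over_many_draws(self, rng):
        cfg = AugmentationConfig()
        for _ in range(300):
            t = sample_rigid(cfg, rng)
            assert max(abs(a) for a in t.angles_deg) <= 10.0
            assert np.linalg.norm(t.translation_mm) <= 30.0

    def test_zero_caps_give_identity(self, rng):
        t = sample_rigid(identity_config(), rng)
        assert t.angles_deg == (0.0, 0.0, 0.0)
        np.testing.assert_allclose(t.translation_mm, 0.0, atol=1e-12)


class TestTPS:
    def test_zero_displacements_give_zero_field(self, rng):
        pts = rng.uniform(0, 10, size=(12, 3))
        model = tps_fit(pts, np.zeros((12, 3)))
        np.testing.assert_allclose(model.dense_field((5, 5, 5)), 0.0, atol=1e-9)

    def test_interpolation_property_at_control_points(self, rng):
        pts = control_grid_points((12, 12, 12), (3, 3, 3))
        disp = rng.uniform(-2, 2, size=pts.shape)
        model = tps_fit(pts, disp)
        np.testing.assert_allclose(model(pts), disp, atol=1e-6)

    def test_dense_field_matches_kernel_sum_oracle(self, rng):
        pts = rng.uniform(0, 11, size=(8, 3))
        disp = rng.uniform(-1.5, 1.5, size=(8, 3))
        model = tps_fit(pts, disp)
        dense = model.dense_field((12, 12, 12))
        oracle = tps_dense_oracle(pts, disp, (12, 12, 12))
        np.testing.assert_allclose(dense, oracle, atol=1e-6)

    def test_cross_check_against_rbf_interpolator(self, rng):
        pts = rng.uniform(0, 9, size=(10, 3))
        disp = rng.uniform(-1, 1, size=(10, 3))
        model = tps_fit(pts, disp)
        grid = np.stack(np.meshgrid(*[np.arange(10.0)] * 3, indexing="ij"))
        q = grid.reshape(3, -1).T
        ref = RBFInterpolator(pts, disp, kernel="linear", degree=1)(q)
        np.testing.assert_allclose(model(q), ref, atol=1e-8)

    def test_degenerate_points_raise(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0], [4, 0, 0]], float)
        with pytest.raises(ValueError):
            tps_fit(pts, np.ones((5, 3)))

    def test_too_few_points_raise(self):
        with pytest.raises(ValueError):
            tps_fit(np.zeros((3, 3)), np.zeros((3, 3)))


class TestSampleNonrigid:
    def test_cap_respected_across_draws(self, rng):
        cfg = AugmentationConfig(control_grid=(4, 4, 4))
        for _ in range(20):
            fld = sample_nonrigid(cfg, (24, 24, 24), rng)
            assert fld.magnitude_mm().max() <= 6.0 + 1e-9

    def test_zero_cap_gives_zero_field(self, rng):
        cfg = AugmentationConfig(max_nonrigid_disp_mm=0.0, control_grid=(3, 3, 3))
        fld = sample_nonrigid(cfg, (10, 10, 10), rng)
        np.testing.assert_array_equal(fld.data, 0.0)

    def test_overshooting_field_rescaled_to_exact_cap(self):
        data = np.zeros((3, 6, 6, 6))
        data[0, 3, 3, 3] = 10.0  # 10 mm at 1 mm spacing
        capped = cap_field(DisplacementField(data), 6.0)
        assert capped.magnitude_mm().max() == pytest.approx(6.0, abs=1e-12)

    def test_field_under_cap_untouched(self):
        data = np.full((3, 4, 4, 4), 0.5)
        capped = cap_field(DisplacementField(data), 6.0)
        np.testing.assert_array_equal(capped.data, data)


class TestIntensityAugment:
    def test_neutral_parameters_are_identity(self, smooth_volume, rng):
        out = intensity_augment(smooth_volume, identity_config(), rng)
        np.testing.assert_allclose(out.data, smooth_volume.data, atol=1e-12)

    def test_gamma_two_squares_half(self, rng):
        cfg = AugmentationConfig(gamma_range=(2.0, 2.0), brightness_frac=0.0)
        vol = Volume(np.full((3, 3, 3), 0.5))
        out = intensity_augment(vol, cfg, rng)
        np.testing.assert_allclose(out.data, 0.25, atol=1e-12)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_output_always_in_unit_range(self, seed):
        r = np.random.default_rng(seed)
        vol = Volume(r.uniform(size=(6, 6, 6)))
        out = intensity_augment(vol, AugmentationConfig(), r)
        assert out.data.min() >= 0.0 and out.data.max() <= 1.0

    def test_unnormalised_input_rejected(self, rng):
        with pytest.raises(ValueError):
            intensity_augment(Volume(np.full((3, 3, 3), 2.0)), AugmentationConfig(), rng)

    def test_gamma_draws_respect_range(self, rng):
        cfg = AugmentationConfig()
        draws = [sample_intensity_params(cfg, rng)[0] for _ in range(500)]
        assert 0.5 <= min(draws) and max(draws) <= 2.0


class TestGeneratePair:
    def test_identity_config_returns_inputs_exactly(self, phantom32, rng):
        fixed, labels = phantom32
        moving, moving_labels, fld = generate_pair(fixed, labels, identity_config(), rng)
        np.testing.assert_array_equal(moving.data, fixed.data)
        np.testing.assert_array_equal(moving_labels.data, labels.data)
        np.testing.assert_array_equal(fld.data, 0.0)

    def test_moving_labels_subset_of_fixed(self, phantom32, rng):
        fixed, labels = phantom32
        _, moving_labels, _ = generate_pair(fixed, labels, desk_augmentation(), rng)
        assert set(np.unique(moving_labels.data)) <= set(np.unique(labels.data))

    def test_bit_reproducible_under_seed(self, phantom32):
        fixed, labels = phantom32
        cfg = desk_augmentation()
        out1 = generate_pair(fixed, labels, cfg, np.random.default_rng(5))
        out2 = generate_pair(fixed, labels, cfg, np.random.default_rng(5))
        np.testing.assert_array_equal(out1[0].data, out2[0].data)
        np.testing.assert_array_equal(out1[1].data, out2[1].data)
        np.testing.assert_array_equal(out1[2].data, out2[2].data)

    def test_generation_writes_nothing_to_disk(self, phantom32, tmp_path, monkeypatch):
        fixed, labels = phantom32
        monkeypatch.chdir(tmp_path)
        monkeypatch.setenv("TMPDIR", str(tmp_path))
        before = set(os.listdir(tmp_path))
        generate_pair(fixed, labels, desk_augmentation(), np.random.default_rng(0))
        assert set(os.listdir(tmp_path)) == before

    def test_inverse_field_recovers_fixed_in_interior(self, phantom32):
        fixed, labels = phantom32
        moving, _, fld = generate_pair(
            fixed, labels, desk_augmentation(), np.random.default_rng(3),
            augment_intensity=False,
        )
        inv = invert_field_oracle(fld.data)
        recovered = warp_volume(moving, DisplacementField(inv))
        interior = (slice(6, -6),) * 3
        assert global_ncc(recovered.data[interior], fixed.data[interior]) > 0.95

    def test_shape_mismatch_rejected(self, phantom32, rng):
        fixed, _ = phantom32
        _, small_labels = generate_phantom((16, 16, 16), 2, np.random.default_rng(0))
        with pytest.raises(ValueError):
            generate_pair(fixed, small_labels, identity_config(), rng)


class TestPhantom:
    def test_deterministic_under_seed(self):
        a = generate_phantom((20, 20, 20), 3, np.random.default_rng(11))
        b = generate_phantom((20, 20, 20), 3, np.random.default_rng(11))
        np.testing.assert_array_equal(a[0].data, b[0].data)
        np.testing.assert_array_equal(a[1].data, b[1].data)

    def test_label_count_is_organs_plus_tube_plus_background(self):
        _, lbl = generate_phantom((28, 28, 28), 4, np.random.default_rng(2))
        assert len(np.unique(lbl.data)) == 4 + 2

    def test_intensities_in_unit_interval(self, phantom32):
        vol, _ = phantom32
        assert vol.data.min() >= 0.0 and vol.data.max() <= 1.0

    def test_too_small_shape_raises(self):
        with pytest.raises(ValueError):
            generate_phantom((8, 8, 8), 2, np.random.default_rng(0))


def test_eval_pairs_reproducible_and_sized(phantom32):
    dataset = [phantom32]
    cfg = desk_augmentation()
    pairs = make_eval_pairs(dataset, cfg, 3, seed=9)
    again = make_eval_pairs(dataset, cfg, 3, seed=9)
    assert len(pairs) == 3
    for p, q in zip(pairs, again):
        assert isinstance(p, EvalPair)
        np.testing.assert_array_equal(p.moving.data, q.moving.data)
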