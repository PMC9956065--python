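"""Loss terms against closed-form values and brute-force oracles, and the
adaptive weighting layer's contracts."""

import numpy as np
import pytest

from oracles import local_ncc_oracle, smoothness_oracle
from voxreg.autodiff import Adam, Tensor
from voxreg.losses import (VARIANTS, AdaptiveLossWeights, global_ncc,
                           hd_surrogate_loss, local_ncc_loss, make_variant,
                           smoothness_reg, soft_dice_loss, ssim3d, ssim_loss)


@pytest.fixture
def smooth_pair(smooth_volume):
    return smooth_volume.data, smooth_volume.data.copy()


class TestLocalNCC:
    def test_identical_nonconstant_inputs_score_zero(self, smooth_pair):
        a, b = smooth_pair
        assert abs(float(local_ncc_loss(a, b, window=5).data)) <= 1e-6

    def test_affine_intensity_invariance(self, smooth_volume):
        a = smooth_volume.data
        b = 2.0 * a + 0.1
        assert abs(float(local_ncc_loss(a, b, window=5).data)) <= 1e-6

    def test_matches_windowed_correlation_oracle(self, rng):
        a = rng.uniform(size=(7, 7, 7))
        b = rng.uniform(size=(7, 7, 7))
        ours = float(local_ncc_loss(a, b, window=3).data)
        assert ours == pytest.approx(local_ncc_oracle(a, b, 3), abs=1e-6)

    def test_even_window_rejected(self, smooth_pair):
        with pytest.raises(ValueError):
            local_ncc_loss(*smooth_pair, window=4)


class TestGlobalNCC:
    def test_self_correlation_is_one(self, smooth_volume):
        assert global_ncc(smooth_volume, smooth_volume) == pytest.approx(1.0)

    def test_anticorrelation_is_minus_one(self, smooth_volume):
        a = smooth_volume.data
        b = 2.0 * a.mean() - a
        assert global_ncc(a, b) == pytest.approx(-1.0)

    def test_matches_direct_formula(self, rng):
        a = rng.normal(size=(5, 5, 5))
        b = rng.normal(size=(5, 5, 5))
        za, zb = a - a.mean(), b - b.mean()
        expected = (za * zb).sum() / np.sqrt((za**2).sum() * (zb**2).sum())
        assert global_ncc(a, b) == pytest.approx(expected, abs=1e-9)

    def test_constant_input_rejected(self, smooth_volume):
        with pytest.raises(ValueError):
            global_ncc(np.ones((4, 4, 4)), smooth_volume.data[:4, :4, :4])


class TestSSIM:
    def test_self_similarity_is_one(self, smooth_volume):
        assert float(ssim3d(smooth_volume, smooth_volume).data) == pytest.approx(1.0, abs=1e-6)

    def test_inverted_binary_grid_is_dissimilar(self, rng):
        a = rng.choice([0.0, 1.0], size=(9, 9, 9))
        val = float(ssim3d(a, 1.0 - a).data)
        assert val < 1.0

    def test_single_window_closed_form(self, rng):
        a = rng.uniform(size=(3, 3, 3))
        b = rng.uniform(size=(3, 3, 3))
        mu_a, mu_b = a.mean(), b.mean()
        va, vb = a.var(), b.var()
        cov = ((a - mu_a) * (b - mu_b)).mean()
        c1, c2 = 0.01**2, 0.03**2
        expected = ((2 * mu_a * mu_b + c1) * (2 * cov + c2)) / (
            (mu_a**2 + mu_b**2 + c1) * (va + vb + c2)
        )
        assert float(ssim3d(a, b, window=3).data) == pytest.approx(expected, abs=1e-9)

    def test_loss_form_is_one_minus_similarity(self, smooth_volume):
        a = smooth_volume.data
        assert float(ssim_loss(a, a).data) == pytest.approx(0.0, abs=1e-6)


class TestSoftDice:
    @staticmethod
    def _onehot(mask):
        return np.stack([1.0 - mask, mask])

    def test_perfect_prediction_scores_zero(self):
        mask = np.zeros((4, 4, 4))
        mask[:2] = 1.0
        enc = self._onehot(mask)
        assert float(soft_dice_loss(enc, enc).data) == pytest.approx(0.0, abs=1e-4)

    def test_disjoint_masks_score_one(self):
        a = np.zeros((4, 4, 4))
        b = np.zeros((4, 4, 4))
        a[0], b[3] = 1.0, 1.0
        loss = float(soft_dice_loss(self._onehot(a), self._onehot(b)).data)
        assert loss == pytest.approx(1.0, abs=1e-3)

    def test_half_overlap_toy_scores_half(self):
        # 4x1x1 grids: prediction covers voxels {0,1}, truth {1,2};
        # Dice = 2*1/(2+2) = 0.5 so the loss is 0.5
        p = np.array([1.0, 1.0, 0.0, 0.0]).reshape(4, 1, 1)
        q = np.array([0.0, 1.0, 1.0, 0.0]).reshape(4, 1, 1)
        loss = float(soft_dice_loss(self._onehot(p), self._onehot(q)).data)
        assert loss == pytest.approx(0.5, abs=1e-4)

    def test_channel_mismatch_rejected(self):
        with pytest.raises(ValueError):
            soft_dice_loss(np.zeros((2, 3, 3, 3)), np.zeros((3, 3, 3, 3)))


class TestHDSurrogate:
    @staticmethod
    def _single_voxel(pos):
        m = np.zeros((12, 12, 12))
        m[pos] = 1.0
        return np.stack([1.0 - m, m])

    def test_perfect_prediction_scores_zero(self):
        enc = self._single_voxel((3, 3, 3))
        assert float(hd_surrogate_loss(enc, enc).data) == pytest.approx(0.0, abs=1e-9)

    def test_monotone_in_offset_distance(self):
        truth = self._single_voxel((2, 2, 2))
        values = [
            float(hd_surrogate_loss(self._single_voxel((2, 2, 2 + d)), truth).data)
            for d in (1, 2, 4, 8)
        ]
        assert all(a < b for a, b in zip(values, values[1:]))

    def test_finite_and_nonnegative_on_random_masks(self, rng):
        p = np.stack([np.zeros((6, 6, 6)), rng.choice([0.0, 1.0], size=(6, 6, 6))])
        p[0] = 1.0 - p[1]
        q = np.stack([np.zeros((6, 6, 6)), rng.choice([0.0, 1.0], size=(6, 6, 6))])
        q[0] = 1.0 - q[1]
        val = float(hd_surrogate_loss(p, q).data)
        assert np.isfinite(val) and val >= 0.0

    def test_empty_truth_class_warns_and_skips(self):
        pred = self._single_voxel((3, 3, 3))
        truth = np.stack([np.ones((12, 12, 12)), np.zeros((12, 12, 12))])
        with pytest.warns(UserWarning):
            val = float(hd_surrogate_loss(pred, truth).data)
        assert val == 0.0


class TestSmoothness:
    def test_constant_field_scores_zero(self):
        assert float(smoothness_reg(np.full((3, 5, 5, 5), 2.0)).data) == 0.0

    def test_unit_ramp_hand_value(self):
        # one component is the ramp i: its forward difference along axis 0
        # is 1 everywhere (mean squared 1); the other eight
        # component/axis combinations vanish, so the mean over nine is 1/9
        fld = np.zeros((3, 4, 4, 4))
        fld[0] = np.arange(4, dtype=float)[:, None, None]
        assert float(smoothness_reg(fld).data) == pytest.approx(1.0 / 9.0, abs=1e-12)

    def test_matches_finite_difference_oracle(self, rng):
        fld = rng.normal(size=(3, 6, 6, 6))
        assert float(smoothness_reg(fld).data) == pytest.approx(
            smoothness_oracle(fld), abs=1e-9
        )


class TestAdaptiveWeights:
    def test_default_init_equal_weights_and_lambda(self):
        w = AdaptiveLossWeights(["ncc", "ssim"], trainable=True)
        np.testing.assert_allclose(w.omega, [0.5, 0.5], atol=1e-12)
        assert w.lam[0] == pytest.approx(5e-3)

    def test_printed_arithmetic_of_combined_total(self):
        w = AdaptiveLossWeights(["a", "b"])
        bundle = w.combine([Tensor(0.2), Tensor(0.4)], [Tensor(2.0)])
        assert float(bundle.total.data) == pytest.approx(0.31, abs=1e-9)
        bundle.check()

    def test_omega_sums_to_one_after_arbitrary_updates(self, rng):
        w = AdaptiveLossWeights(["a", "b", "c"], trainable=True)
        opt = Adam(w.parameters(), lr=0.05)
        for _ in range(25):
            bundle = w.combine(
                [Tensor(v) for v in rng.uniform(0.1, 1.0, 3)], [Tensor(0.5)]
            )
            opt.zero_grad()
            bundle.total.backward()
            opt.step()
        assert w.omega.sum() == pytest.approx(1.0, abs=1e-6)
        assert np.all(w.omega >= 0)

    def test_frozen_weights_do_not_move(self, rng):
        w = AdaptiveLossWeights(["a", "b"], trainable=False)
        assert w.parameters() == []
        before = w.omega.copy()
        bundle = w.combine([Tensor(0.3), Tensor(0.6)], [Tensor(1.0)])
        bundle.total.backward()
        np.testing.assert_array_equal(w.omega, before)

    def test_combine_is_linear_in_each_loss(self):
        w = AdaptiveLossWeights(["a", "b"])
        base = float(w.combine([Tensor(0.2), Tensor(0.4)], [Tensor(0.0)]).total.data)
        bumped = float(w.combine([Tensor(1.2), Tensor(0.4)], [Tensor(0.0)]).total.data)
        assert bumped - base == pytest.approx(w.omega[0] * 1.0, abs=1e-9)

    def test_length_mismatch_rejected(self):
        w = AdaptiveLossWeights(["a", "b"])
        with pytest.raises(ValueError):
            w.combine([Tensor(0.1)], [Tensor(0.0)])


class TestVariantFactory:
    def test_design_matrix_coverage(self):
        expected = {
            "bl-n": ("ncc",),
            "bl-ns": ("ncc", "ssim"),
            "sg-nd": ("ncc", "dice"),
            "sg-nsd": ("ncc", "ssim", "dice"),
            "uw-nsd": ("ncc", "ssim", "dice"),
            "uw-nsdh": ("ncc", "ssim", "dice", "hd"),
        }
        assert set(VARIANTS) == set(expected)
        for name, losses in expected.items():
            v = make_variant(name)
            assert v.loss_names == losses
            assert v.weights.trainable == name.startswith("uw")
            assert v.weights.reg_names == ["smooth"]

    def test_segmentation_guidance_flag(self):
        assert not make_variant("bl-ns").uses_labels
        assert make_variant("sg-nd").uses_labels

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            make_variant("bl-x")
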