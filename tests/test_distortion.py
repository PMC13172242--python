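"""Distortion simulator: field sampling, Jacobian, warps, presets, replay."""

import numpy as np
import pytest

import dwidistort as dd
from dwidistort.distortion import (
    DisplacementField,
    RigidParams,
    sample_displacement_field,
    severity_presets,
    training_preset,
)
from dwidistort.image import SliceImage


def delta_image(shape=(64, 64), at=(32, 32), spacing=(0.5, 0.5)):
    data = np.zeros(shape)
    data[at] = 1.0
    return SliceImage(data, spacing)


class TestSampleDisplacementField:
    def test_zero_sigma_gives_identically_zero_field(self):
        f = sample_displacement_field((64, 64), 32, 0.0, None, seed=0)
        assert not f.dense.any()

    def test_all_false_region_zeroes_field_regardless_of_sigma(self):
        f = sample_displacement_field(
            (64, 64), 32, 10.0, np.zeros((64, 64), bool), seed=1
        )
        assert not f.dense.any()

    def test_dense_zero_outside_region(self):
        region = np.zeros((96, 96), bool)
        region[40:80, 20:70] = True
        for seed in range(5):
            f = sample_displacement_field((96, 96), 32, 10.0, region, seed=seed)
            assert not f.dense[:, ~region].any()
            assert f.dense[:, region].any()

    def test_coarse_node_standard_deviation(self):
        """Monte-Carlo moment check: node values are Normal(0, sigma^2)."""
        sigma = 10.0
        vals = []
        for seed in range(600):
            f = sample_displacement_field((64, 64), 32, sigma, None, seed=seed)
            vals.append(f.coarse.ravel())
        vals = np.concatenate(vals)
        assert vals.size >= 10_000
        assert abs(vals.std() - sigma) / sigma < 0.03

    def test_parameter_errors(self):
        with pytest.raises(ValueError, match="sigma"):
            sample_displacement_field((64, 64), 32, -1.0, None, seed=0)
        with pytest.raises(ValueError, match="grid_spacing"):
            sample_displacement_field((64, 64), 0, 1.0, None, seed=0)


class TestJacobian:
    def test_zero_field_gives_unit_jacobian(self):
        f = DisplacementField.from_dense(np.zeros((2, 32, 32)))
        assert np.array_equal(dd.jacobian_determinant(f).values, np.ones((32, 32)))

    @pytest.mark.parametrize(
        "a,b,c,d",
        [(0.1, -0.05, 0.0, 0.0), (0.0, 0.0, 0.2, 0.1), (0.05, 0.05, -0.1, 0.02)],
    )
    def test_affine_field_analytic_value(self, a, b, c, d):
        rows, cols = np.indices((40, 40), dtype=float)
        dense = np.stack([a * cols + c * rows, d * cols + b * rows])
        j = dd.jacobian_determinant(DisplacementField.from_dense(dense)).values
        expected = (1 + a) * (1 + b) - c * d
        np.testing.assert_allclose(j[1:-1, 1:-1], expected, atol=1e-10)

    def test_matches_bruteforce_stencil_on_random_smooth_field(self):
        """Independent per-pixel finite-difference oracle."""
        f = sample_displacement_field((64, 64), 16, 5.0, None, seed=9)
        j = dd.jacobian_determinant(f).values
        u_x, u_y = f.dense

        def d_dx(u, i, k):  # column derivative, one-sided at borders
            if k == 0:
                return u[i, 1] - u[i, 0]
            if k == u.shape[1] - 1:
                return u[i, k] - u[i, k - 1]
            return (u[i, k + 1] - u[i, k - 1]) / 2.0

        def d_dy(u, i, k):
            if i == 0:
                return u[1, k] - u[0, k]
            if i == u.shape[0] - 1:
                return u[i, k] - u[i - 1, k]
            return (u[i + 1, k] - u[i - 1, k]) / 2.0

        for i in range(0, 64, 7):
            for k in range(0, 64, 7):
                expected = (1 + d_dx(u_x, i, k)) * (1 + d_dy(u_y, i, k)) - d_dy(
                    u_x, i, k
                ) * d_dx(u_y, i, k)
                assert abs(j[i, k] - expected) < 1e-10


class TestElasticWarp:
    def test_zero_field_is_bit_exact_identity(self, noisy_case):
        f = DisplacementField.from_dense(np.zeros((2,) + noisy_case.dwi.shape))
        out = dd.apply_elastic(noisy_case.dwi.channel(0), f)
        assert np.array_equal(out.data, noisy_case.dwi.channel(0).data)

    def test_constant_field_shifts_delta_along_ap_axis(self):
        """Backward mapping: u = (0, +k) moves content k pixels anteriorly."""
        k = 5.0
        img = delta_image()
        dense = np.zeros((2, 64, 64))
        dense[1] = k
        out = dd.apply_elastic(img, DisplacementField.from_dense(dense))
        # output at p samples input at p + k rows -> delta appears at row 32-k
        assert out.data[27, 32] == 1.0
        assert out.data.sum() == 1.0

    def test_mask_mode_stays_binary(self, noisy_case):
        f = sample_displacement_field(
            noisy_case.dwi.shape, 32, 8.0,
            dd.rectal_adjacent_region(noisy_case, 10.0).data, seed=2,
        )
        out = dd.apply_elastic(noisy_case.prostate_mask, f, interpolation_mode="mask")
        assert set(np.unique(out.data.astype(int))) <= {0, 1}

    def test_shape_mismatch_raises(self, noisy_case):
        f = DisplacementField.from_dense(np.zeros((2, 8, 8)))
        with pytest.raises(ValueError, match="shape"):
            dd.apply_elastic(noisy_case.dwi.channel(0), f)


class TestModulateIntensity:
    def test_unit_jacobian_identity(self, noisy_case):
        f = DisplacementField.from_dense(np.zeros((2,) + noisy_case.dwi.shape))
        jac = dd.jacobian_determinant(f)
        img = noisy_case.dwi.channel(0)
        assert np.array_equal(dd.modulate_intensity(img, jac).data, img.data)

    def test_scalar_jacobian(self):
        img = SliceImage(np.full((16, 16), 5.0))
        jac = dd.JacobianMap(values=np.full((16, 16), 2.0))
        assert (dd.modulate_intensity(img, jac).data == 10.0).all()

    def test_mass_conservation_small_sigma(self, noisy_case):
        """Elastic warp + |J| modulation approximately conserves total signal."""
        img = noisy_case.dwi.channel(0)
        region = dd.rectal_adjacent_region(noisy_case, 10.0).data
        interior = (slice(1, -1), slice(1, -1))
        ref = img.data[interior].sum()
        for seed in range(8):
            f = sample_displacement_field(img.shape, 32, 3.0, region, seed=seed)
            warped = dd.modulate_intensity(
                dd.apply_elastic(img, f), dd.jacobian_determinant(f)
            )
            assert abs(warped.data[interior].sum() - ref) / ref < 0.02


class TestApplyRigid:
    def test_identity_is_bit_exact(self, noisy_case):
        img = noisy_case.dwi.channel(1)
        out = dd.apply_rigid(img, RigidParams())
        assert np.array_equal(out.data, img.data)

    def test_90_degree_rotation_matches_remap_oracle(self, rng):
        data = rng.random((33, 33))
        img = SliceImage(data, (0.5, 0.5))
        out = dd.apply_rigid(img, RigidParams(rotation_deg=90.0))
        # brute-force oracle: source offset = R(-90) * output offset
        oracle = np.zeros_like(data)
        c = 16
        for i in range(33):
            for k in range(33):
                src_r, src_c = c + (k - c), c - (i - c)
                oracle[i, k] = data[src_r, src_c]
        np.testing.assert_allclose(out.data, oracle, atol=1e-9)

    def test_2mm_translation_is_4px_shift(self):
        img = delta_image()
        out = dd.apply_rigid(img, RigidParams(translation_mm=(0.0, 2.0)))
        assert out.data[36, 32] == 1.0
        assert out.data.sum() == 1.0

    def test_ap_scale_stretches_delta(self):
        img = delta_image(at=(22, 32))
        out = dd.apply_rigid(img, RigidParams(ap_scale=2.0), "mask")
        # point at row offset -9.5 from centre 31.5 maps to offset -19
        assert out.data[int(31.5 - 2 * 9.5 - 0.5), 32] == 1.0

    def test_unknown_interpolation_mode(self, noisy_case):
        with pytest.raises(ValueError, match="interpolation mode"):
            dd.apply_rigid(noisy_case.dwi.channel(0), RigidParams(), "cubic")

    def test_bad_scale_rejected(self):
        with pytest.raises(ValueError, match="ap_scale"):
            RigidParams(ap_scale=0.0)


class TestPresets:
    def test_exactly_four_severity_levels(self):
        presets = severity_presets()
        assert list(presets) == ["mild", "moderate", "severe", "extreme"]
        assert [p.sigma_px for p in presets.values()] == [3.0, 5.0, 7.0, 10.0]

    def test_translation_ranges_within_2mm(self):
        for p in severity_presets().values():
            lo, hi = p.translation_mm_range
            assert 0.0 <= lo <= hi <= 2.0

    def test_training_ranges(self):
        p = training_preset()
        assert p.sigma_px == 10.0
        assert p.ap_scale_ranges == ((0.9, 1.1),)
        assert p.rotation_deg_range == (0.0, 15.0)

    @pytest.mark.parametrize("name", ["mild", "moderate", "severe", "extreme"])
    def test_drawn_parameters_lie_in_declared_ranges(self, name, noisy_case):
        p = severity_presets()[name]
        for seed in range(10):
            _, _, rec = dd.simulate_distortion(noisy_case, name, seed=seed)
            assert rec.field.sigma_px == p.sigma_px
            assert any(
                lo <= rec.rigid.ap_scale <= hi for lo, hi in p.ap_scale_ranges
            )
            lo, hi = p.rotation_deg_range
            assert lo <= abs(rec.rigid.rotation_deg) <= hi
            lo, hi = p.translation_mm_range
            for t in rec.rigid.translation_mm:
                assert lo <= abs(t) <= hi

    def test_unknown_preset_lists_valid_names(self, noisy_case):
        with pytest.raises(ValueError, match="mild"):
            dd.simulate_distortion(noisy_case, "catastrophic", seed=0)


class TestSimulateDistortion:
    def test_degenerate_preset_is_bit_exact_fixed_point(
        self, noisy_case, identity_preset
    ):
        distorted, masks, rec = dd.simulate_distortion(
            noisy_case, identity_preset, seed=5
        )
        assert np.array_equal(distorted.data, noisy_case.dwi.data)
        for name, m in masks.items():
            assert np.array_equal(
                m.data.astype(bool), noisy_case.masks()[name].data.astype(bool)
            )
        assert dd.dice(masks["prostate"], noisy_case.prostate_mask) == 1.0

    def test_replaying_record_is_bit_exact(self, noisy_case):
        distorted, masks, rec = dd.simulate_distortion(
            noisy_case, "severe", seed=21
        )
        for i in range(noisy_case.dwi.n_channels):
            replay = rec.transform_image(noisy_case.dwi.channel(i))
            assert np.array_equal(replay.data, distorted.data[i])
        replay_mask = rec.transform_mask(noisy_case.prostate_mask)
        assert np.array_equal(replay_mask.data, masks["prostate"].data)

    def test_same_seed_reproduces_same_draw(self, noisy_case):
        d1, _, r1 = dd.simulate_distortion(noisy_case, "moderate", seed=4)
        d2, _, r2 = dd.simulate_distortion(noisy_case, "moderate", seed=4)
        assert np.array_equal(d1.data, d2.data)
        assert r1.rigid == r2.rigid

    def test_all_channels_share_one_transform(self, noiseless_case):
        """A constant-ratio pair of channels stays constant-ratio."""
        distorted, _, _ = dd.simulate_distortion(noiseless_case, "severe", seed=8)
        # channels of the noiseless phantom are warped identically, so zero
        # pixels coincide across channels
        zeros0 = distorted.data[0] == 0
        zeros2 = distorted.data[2] == 0
        assert np.array_equal(zeros0, zeros2)
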