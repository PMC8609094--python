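import numpy as np
import pytest

from rishharm import (
    apply_scale_maps,
    build_sh_basis,
    compute_rish,
    fit_sh,
    group_mean_rish,
    harmonize_subject,
    learn_scale_maps,
)
from rishharm.gradients import rotate_scheme
from rishharm.rish import RISHFeatureMap, ScaleMapSet
from rishharm.sh import SHCoefficientField, n_coefficients
from rishharm.volume import DWIVolume

from conftest import make_scheme, tensor_attenuation


def coeff_field(data, l_max=4):
    shape = data.shape[:3]
    return SHCoefficientField(data, l_max, np.ones(shape, bool), np.ones(shape))


def rish_map(data, l_max=4):
    return RISHFeatureMap(np.asarray(data, float), l_max,
                          np.ones(np.asarray(data).shape[:3], bool))


def tensor_dwi(scheme, evals=(1.7e-3, 0.3e-3, 0.3e-3), shape=(3, 2, 2), s0=100.0):
    atten = tensor_attenuation(scheme.directions, scheme.shell_bvalue, evals)
    data = np.zeros(shape + (scheme.n_volumes,))
    data[..., scheme.b0_mask] = s0
    data[..., ~scheme.b0_mask] = s0 * atten
    return DWIVolume(data, scheme, np.ones(shape, dtype=bool))


class TestComputeRish:
    def test_zero_coefficients_give_zero_energy(self):
        e = compute_rish(coeff_field(np.zeros((2, 2, 2, 15))))
        np.testing.assert_array_equal(e.data, 0.0)

    def test_constant_signal_energy_is_4pi_at_order_zero(self):
        scheme = make_scheme(45, 1000.0)
        data = np.zeros((2, 2, 1) + (scheme.n_volumes,))
        data[:] = 100.0
        dwi = DWIVolume(data, scheme, np.ones((2, 2, 1), bool))
        e = compute_rish(fit_sh(dwi, l_max=4, reg_lambda=0.0))
        assert e.data[0, 0, 0, 0] == pytest.approx(4 * np.pi, rel=1e-10)
        np.testing.assert_allclose(e.data[..., 1:], 0.0, atol=1e-18)

    @staticmethod
    def _rotation():
        return np.array([[np.cos(0.6), -np.sin(0.6), 0],
                         [np.sin(0.6), np.cos(0.6), 0], [0, 0, 1.0]]) @ \
            np.array([[1.0, 0, 0],
                      [0, np.cos(0.4), -np.sin(0.4)], [0, np.sin(0.4), np.cos(0.4)]])

    def test_rotation_invariance_for_band_limited_signal(self):
        # a signal representable at l<=4: refitting the rotated function on
        # the same scheme must leave every per-order energy unchanged
        from rishharm import build_sh_basis, fit_sh_signal

        scheme = make_scheme(60, 1000.0)
        dirs = scheme.directions
        c = fit_sh_signal(tensor_attenuation(dirs, 1000.0, [1.7e-3, 0.3e-3, 0.3e-3]),
                          dirs, 4, reg_lambda=0.0)
        R = self._rotation()
        c_rot = fit_sh_signal(build_sh_basis(dirs @ R, 4) @ c, dirs, 4, reg_lambda=0.0)

        def energies(cv):
            return np.array([np.sum(cv[s] ** 2) for s in (slice(0, 1), slice(1, 6), slice(6, 15))])

        np.testing.assert_allclose(energies(c_rot), energies(c), rtol=1e-10)

    def test_rotation_invariance_for_raw_tensor_signal(self):
        # raw monoexponential signal carries l>=6 content that aliases into
        # the fitted band differently per sampling: invariance holds to the
        # truncation-aliasing level
        scheme = make_scheme(60, 1000.0)
        e_plain = compute_rish(fit_sh(tensor_dwi(scheme), l_max=4, reg_lambda=0.0))
        rot = rotate_scheme(scheme, self._rotation())
        e_rot = compute_rish(fit_sh(tensor_dwi(rot), l_max=4, reg_lambda=0.0))
        np.testing.assert_allclose(e_rot.data[0, 0, 0], e_plain.data[0, 0, 0], rtol=5e-3)


class TestGroupMean:
    def test_single_map_no_smoothing_is_identity(self):
        m = rish_map(np.random.default_rng(0).random((3, 3, 2, 3)))
        out = group_mean_rish([m], smoothing_fwhm=0.0)
        np.testing.assert_allclose(out.data, m.data)

    def test_two_map_mean(self):
        a = rish_map(np.full((2, 2, 1, 3), 2.0))
        b = rish_map(np.full((2, 2, 1, 3), 4.0))
        out = group_mean_rish([a, b], smoothing_fwhm=0.0)
        np.testing.assert_allclose(out.data, 3.0)

    def test_grid_mismatch_raises(self):
        a = rish_map(np.ones((2, 2, 1, 3)))
        b = rish_map(np.ones((3, 2, 1, 3)))
        with pytest.raises(ValueError, match="different grids"):
            group_mean_rish([a, b])

    def test_small_group_warns(self):
        with pytest.warns(UserWarning, match="training subjects"):
            group_mean_rish([rish_map(np.ones((2, 2, 1, 3)))] * 3, smoothing_fwhm=0.0)


class TestLearnScaleMaps:
    def test_identical_means_give_unit_maps(self):
        m = rish_map(np.random.default_rng(1).random((3, 3, 2, 3)) + 0.5)
        delta = learn_scale_maps(m, m)
        np.testing.assert_allclose(delta.data, 1.0, rtol=1e-12)

    def test_quarter_energy_gives_half_scale(self):
        ref = rish_map(np.full((2, 2, 1, 3), 1.0))
        tar = rish_map(np.full((2, 2, 1, 3), 4.0))
        delta = learn_scale_maps(ref, tar, eps=1e-12)
        np.testing.assert_allclose(delta.data, 0.5, rtol=1e-9)

    def test_zero_target_energy_hits_clip_bound(self):
        ref = rish_map(np.ones((2, 2, 1, 3)))
        tar = rish_map(np.zeros((2, 2, 1, 3)))
        delta = learn_scale_maps(ref, tar, eps=1e-8, clip=(0.1, 10.0))
        # raw ratio would be 1e4; the returned value is the clip high bound
        np.testing.assert_allclose(delta.data, 10.0)

    def test_invalid_parameters(self):
        m = rish_map(np.ones((2, 2, 1, 3)))
        with pytest.raises(ValueError, match="eps"):
            learn_scale_maps(m, m, eps=0.0)
        with pytest.raises(ValueError, match="clip"):
            learn_scale_maps(m, m, clip=(2.0, 1.0))
        with pytest.raises(ValueError, match="different grids"):
            learn_scale_maps(m, rish_map(np.ones((2, 2, 2, 3))))

    def test_noise_correction_subtracts_noise_energy(self):
        shape = (2, 2, 1, 3)
        ref = RISHFeatureMap(np.full(shape, 2.0), 4, np.ones(shape[:3], bool),
                             noise_energy=np.full(shape, 1.0))
        tar = RISHFeatureMap(np.full(shape, 4.0), 4, np.ones(shape[:3], bool),
                             noise_energy=np.full(shape, 0.0))
        delta = learn_scale_maps(ref, tar, eps=1e-12, noise_correct=True)
        np.testing.assert_allclose(delta.data, 0.5, rtol=1e-6)  # (2-1)/(4-0)
        delta_raw = learn_scale_maps(ref, tar, eps=1e-12, noise_correct=False)
        np.testing.assert_allclose(delta_raw.data, np.sqrt(0.5), rtol=1e-6)


class TestApplyScaleMaps:
    def test_unit_maps_leave_coefficients_untouched(self):
        rng = np.random.default_rng(2)
        c = coeff_field(rng.normal(size=(2, 2, 2, 15)))
        ones = ScaleMapSet(np.ones((2, 2, 2, 3)), 4, np.ones((2, 2, 2), bool))
        out = apply_scale_maps(c, ones)
        np.testing.assert_array_equal(out.data, c.data)

    def test_energy_scales_with_delta_squared_exactly(self):
        rng = np.random.default_rng(3)
        c = coeff_field(rng.normal(size=(3, 2, 2, 15)))
        delta = ScaleMapSet(rng.uniform(0.5, 2.0, (3, 2, 2, 3)), 4,
                            np.ones((3, 2, 2), bool))
        e_before = compute_rish(c)
        e_after = compute_rish(apply_scale_maps(c, delta))
        np.testing.assert_allclose(e_after.data, delta.data ** 2 * e_before.data,
                                   rtol=1e-14, atol=0)

    def test_order_mismatch_raises(self):
        c = coeff_field(np.ones((2, 2, 2, 15)))
        wrong = ScaleMapSet(np.ones((2, 2, 2, 2)), 2, np.ones((2, 2, 2), bool))
        with pytest.raises(ValueError, match="orders"):
            apply_scale_maps(c, wrong)

    def test_self_harmonization_is_identity_on_energies(self):
        scheme = make_scheme(45, 1000.0)
        dwi = tensor_dwi(scheme)
        e = compute_rish(fit_sh(dwi, l_max=4, reg_lambda=0.0))
        mean = group_mean_rish([e], smoothing_fwhm=0.0)
        delta = learn_scale_maps(mean, mean)
        e2 = compute_rish(apply_scale_maps(fit_sh(dwi, l_max=4, reg_lambda=0.0), delta))
        np.testing.assert_allclose(e2.data, e.data, rtol=1e-12, atol=1e-18)


class TestHarmonizeSubject:
    def test_identity_maps_give_sh_smoothed_roundtrip(self):
        scheme = make_scheme(45, 1000.0, n_b0=2)
        dwi = tensor_dwi(scheme)
        ones = ScaleMapSet(np.ones(dwi.shape + (3,)), 4, np.ones(dwi.shape, bool))
        out = harmonize_subject(dwi, ones, l_max=4, reg_lambda=0.0)
        coeffs = fit_sh(dwi, l_max=4, reg_lambda=0.0)
        from rishharm.sh import reconstruct_signal

        expected = reconstruct_signal(coeffs, scheme.directions)
        np.testing.assert_allclose(out.dw_data(), expected, rtol=1e-10)
        # b0 volumes pass through unchanged
        np.testing.assert_array_equal(out.data[..., scheme.b0_mask],
                                      dwi.data[..., scheme.b0_mask])

    def test_none_scales_mean_identity_projection(self):
        scheme = make_scheme(45, 1000.0)
        dwi = tensor_dwi(scheme)
        ones = ScaleMapSet(np.ones(dwi.shape + (3,)), 4, np.ones(dwi.shape, bool))
        np.testing.assert_allclose(harmonize_subject(dwi, None, l_max=4).data,
                                   harmonize_subject(dwi, ones, l_max=4).data, rtol=1e-12)

    def test_metadata_contract_preserved(self):
        scheme = make_scheme(32, 1000.0, n_b0=3)
        dwi = tensor_dwi(scheme, shape=(4, 3, 2))
        dwi.affine[0, 3] = 12.0
        ones = ScaleMapSet(np.ones((4, 3, 2, 3)), 4, np.ones((4, 3, 2), bool))
        out = harmonize_subject(dwi, ones, l_max=4)
        assert out.shape == dwi.shape
        assert out.data.shape[3] == dwi.data.shape[3]
        np.testing.assert_array_equal(out.affine, dwi.affine)
        np.testing.assert_array_equal(out.mask, dwi.mask)
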