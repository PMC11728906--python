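import numpy as np
import pytest
from scipy import ndimage

from octcoreg import OCTVolume, StressStrainCurve, ValidationError
from octcoreg.phantom import simulate_compression_pair
from octcoreg.qme import (
    DisplacementVolume,
    compute_strain,
    elasticity,
    estimate_displacement,
    layer_stress,
    mask_invalid,
    qme_chain,
)

META = dict(spacing_z_um=10.0, spacing_y_um=20.0, spacing_x_um=20.0)


def _speckle_volume(nz=100, ny=10, nx=10, seed=0, pad=12):
    """Band-limited speckle with padding so shifted copies share content."""
    rng = np.random.default_rng(seed)
    base = ndimage.gaussian_filter1d(rng.exponential(1.0, (nz + 2 * pad, ny, nx)), 1.5, axis=0)
    return base, pad


class TestEstimateDisplacement:
    def test_integer_shift_recovered(self):
        base, pad = _speckle_volume()
        pre = OCTVolume(base[pad : pad + 100], **META)
        post = OCTVolume(base[pad - 2 : pad + 98], **META)  # post[z] = pre[z-2]
        disp = estimate_displacement(pre, post)
        err = np.abs(disp.uz_um[10:-10] / 10.0 - 2.0)
        assert np.median(err) <= 0.05

    def test_zero_shift_gives_zero(self):
        base, pad = _speckle_volume(seed=1)
        pre = OCTVolume(base[pad : pad + 100], **META)
        disp = estimate_displacement(pre, pre)
        assert np.abs(disp.uz_um).max() <= 1e-9
        assert disp.confidence.min() > 0.99

    @pytest.mark.parametrize("shift", [0.25, 0.5, 1.3])
    def test_subvoxel_shift_within_tenth_voxel(self, shift):
        base, pad = _speckle_volume(seed=2)
        coef = ndimage.spline_filter1d(base, order=3, axis=0)
        shifted = ndimage.shift(coef, (shift, 0, 0), order=3, prefilter=False)
        pre = OCTVolume(np.clip(base[pad : pad + 100], 0, None), **META)
        post = OCTVolume(np.clip(shifted[pad : pad + 100], 0, None), **META)
        disp = estimate_displacement(pre, post)
        med = np.median(disp.uz_um[15:-15] / 10.0)
        assert abs(med - shift) <= 0.1

    def test_shape_mismatch_rejected(self):
        a = OCTVolume(np.ones((10, 4, 4)), **META)
        b = OCTVolume(np.ones((12, 4, 4)), **META)
        with pytest.raises(ValidationError):
            estimate_displacement(a, b)

    def test_window_larger_than_depth_rejected(self):
        a = OCTVolume(np.ones((5, 4, 4)), **META)
        with pytest.raises(ValidationError):
            estimate_displacement(a, a, window_um=1000.0)


class TestComputeStrain:
    def _disp(self, uz):
        conf = np.ones_like(uz)
        return DisplacementVolume(uz_um=uz, confidence=conf, **META)

    def test_linear_displacement_constant_slope(self):
        z = np.arange(80)[:, None, None] * 10.0
        uz = np.broadcast_to(0.01 * z, (80, 5, 5)).copy()
        strain = compute_strain(self._disp(uz), fit_window_um=100.0)
        np.testing.assert_allclose(strain[5:-5], 0.01, rtol=1e-9)

    def test_constant_displacement_zero_strain(self):
        uz = np.full((60, 4, 4), 7.0)
        strain = compute_strain(self._disp(uz), fit_window_um=100.0)
        np.testing.assert_allclose(strain[5:-5], 0.0, atol=1e-12)

    def test_piecewise_slope_transition_within_window(self):
        nz = 120
        z = np.arange(nz) * 10.0
        u = np.where(z < 600, 0.01 * z, 0.01 * 600 + 0.02 * (z - 600))
        uz = np.broadcast_to(u[:, None, None], (nz, 3, 3)).copy()
        strain = compute_strain(self._disp(uz), fit_window_um=100.0)
        w_half = 5
        bp = 60
        np.testing.assert_allclose(strain[10 : bp - w_half - 1], 0.01, rtol=1e-6)
        np.testing.assert_allclose(strain[bp + w_half + 1 : -10], 0.02, rtol=1e-6)
        mid = strain[bp - w_half : bp + w_half + 1, 0, 0]
        assert ((mid >= 0.01 - 1e-9) & (mid <= 0.02 + 1e-9)).all()

    def test_zero_confidence_window_is_invalid(self):
        uz = np.zeros((40, 3, 3))
        conf = np.zeros_like(uz)
        strain = compute_strain(DisplacementVolume(uz_um=uz, confidence=conf, **META), fit_window_um=100.0)
        assert np.isnan(strain).all()


class TestLayerStress:
    def test_linear_curve(self):
        curve = StressStrainCurve(np.array([0.0, 0.2]), np.array([0.0, 10.0]))  # sigma = 50 eps
        assert layer_stress(0.10, curve) == pytest.approx(5.0)
        assert layer_stress(0.0, curve) == pytest.approx(0.0)

    def test_nonlinear_matches_hand_interpolation(self):
        curve = StressStrainCurve(np.array([0.0, 0.1, 0.3]), np.array([0.0, 1.0, 5.0]))
        # between the 2nd and 3rd knot: 1 + (0.2-0.1)/(0.3-0.1)*(5-1) = 3.0
        assert layer_stress(0.2, curve) == pytest.approx(3.0)

    def test_out_of_range_raises_without_extrapolation(self):
        curve = StressStrainCurve(np.array([0.0, 0.1]), np.array([0.0, 1.0]))
        with pytest.raises(ValidationError):
            layer_stress(0.5, curve)
        assert layer_stress(0.5, curve, extrapolate=True) == pytest.approx(5.0)


class TestElasticity:
    def test_ratio(self):
        E = elasticity(np.full((4, 4), 1.0), np.full((10, 4, 4), 0.1))
        np.testing.assert_allclose(E.E_kPa, 10.0)
        assert E.valid.all()

    def test_zero_strain_marked_invalid(self):
        strain = np.full((10, 4, 4), 0.1)
        strain[3] = 0.0
        E = elasticity(np.full((4, 4), 1.0), strain)
        assert not E.valid[3].any()
        assert np.isnan(E.E_kPa[3]).all()
        assert E.valid[4].all()

    def test_negative_modulus_masked_not_raised(self):
        E = elasticity(np.full((2, 2), 1.0), np.full((5, 2, 2), -0.05))
        assert not E.valid.any()


class TestMasking:
    def test_non_contact_columns_fully_masked(self):
        E = elasticity(np.full((6, 6), 1.0), np.full((20, 6, 6), 0.05))
        vol = OCTVolume(np.ones((20, 6, 6)), **META)
        layer_strain = np.full((6, 6), 0.01)
        layer_strain[:, :3] = 0.0  # no load transmitted: non-contact
        masked = mask_invalid(E, vol, layer_strain=layer_strain)
        assert not masked.valid[:, :, :3].any()
        assert masked.valid[:, :, 3:].any()

    def test_mask_is_monotone_in_threshold(self, flat_qme_phantom, linear_layer_curve):
        wf, truth = flat_qme_phantom
        pre, post, ct = simulate_compression_pair(wf, truth, linear_layer_curve, 500.0, 30.0)
        E, extras = qme_chain(pre, post, linear_layer_curve, 500.0, mask=False)
        loose = mask_invalid(E, pre, adipose_db_threshold=-6.0, layer_strain=extras["layer_strain"])
        tight = mask_invalid(E, pre, adipose_db_threshold=-1.0, layer_strain=extras["layer_strain"])
        # raising the threshold can only mask more voxels
        assert not (tight.valid & ~loose.valid).any()
        assert loose.valid.sum() >= tight.valid.sum()


class TestChainProperties:
    def test_elasticity_invariant_to_intensity_rescaling(self, flat_qme_phantom, linear_layer_curve):
        wf, truth = flat_qme_phantom
        pre, post, _ = simulate_compression_pair(wf, truth, linear_layer_curve, 500.0, 30.0)
        E1, _ = qme_chain(pre, post, linear_layer_curve, 500.0, mask=False)
        pre2 = pre.with_intensity(pre.intensity * 7.5)
        post2 = post.with_intensity(post.intensity * 7.5)
        E2, _ = qme_chain(pre2, post2, linear_layer_curve, 500.0, mask=False)
        a, b = E1.E_kPa[E1.valid & E2.valid], E2.E_kPa[E1.valid & E2.valid]
        np.testing.assert_allclose(a, b, rtol=1e-3)

    def test_chain_conservation_stress_equals_E_times_strain(self, flat_qme_phantom, linear_layer_curve):
        wf, truth = flat_qme_phantom
        pre, post, ct = simulate_compression_pair(wf, truth, linear_layer_curve, 500.0, 30.0)
        E, extras = qme_chain(pre, post, linear_layer_curve, 500.0, mask=False)
        sel = E.valid
        prod = E.E_kPa[sel] * extras["strain"][sel]
        stress = np.broadcast_to(extras["stress_kPa"], E.E_kPa.shape)[sel]
        np.testing.assert_allclose(prod, stress, rtol=0.01)
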