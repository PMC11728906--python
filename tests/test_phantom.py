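import numpy as np
import pytest

from octcoreg import ValidationError
from octcoreg.phantom import (
    Degrade,
    PhantomSpec,
    RigidPose2D,
    SutureSpec,
    TubularFeature,
    extract_tile,
    generate_histology_sections,
    generate_shaving_phantom,
    simulate_compression_pair,
)
from octcoreg.volume_io import StressStrainCurve


def _flat_spec(**kwargs):
    base = dict(
        extent_um=(3000.0, 3000.0, 900.0),
        spacing_lateral_um=30.0,
        spacing_axial_um=10.0,
        seed=0,
        suture=SutureSpec(present=False),
        surface_topography_amplitude_um=0.0,
    )
    base.update(kwargs)
    return PhantomSpec(**base)


class TestGenerator:
    def test_determinism_same_seed(self):
        a, _ = generate_shaving_phantom(_flat_spec(seed=7))
        b, _ = generate_shaving_phantom(_flat_spec(seed=7))
        np.testing.assert_array_equal(a.intensity, b.intensity)

    def test_different_seed_differs(self):
        a, _ = generate_shaving_phantom(_flat_spec(seed=7))
        b, _ = generate_shaving_phantom(_flat_spec(seed=8))
        assert not np.array_equal(a.intensity, b.intensity)

    def test_zero_adipose_fraction_all_dense(self):
        _, truth = generate_shaving_phantom(_flat_spec(adipose_fraction=0.0))
        assert (truth.tissue_class == 0).all()

    @pytest.mark.parametrize("target", [0.2, 0.3, 0.5])
    def test_realized_adipose_fraction(self, target):
        _, truth = generate_shaving_phantom(_flat_spec(adipose_fraction=target, seed=4))
        assert abs(truth.tissue_class.mean() - target) <= 0.05

    def test_dense_brighter_than_adipose(self, small_phantom):
        _, wf, truth = small_phantom
        adip = truth.tissue_class.astype(bool)
        shallow = wf.intensity[20:50]
        assert shallow[:, ~adip].mean() > 2 * shallow[:, adip].mean()

    def test_dense_attenuates_with_depth(self):
        wf, truth = generate_shaving_phantom(_flat_spec(adipose_fraction=0.0, attenuation_per_mm=2.0))
        surf = int(np.median(truth.surface_depth_um) / 10)
        shallow = wf.intensity[surf + 5 : surf + 15].mean()
        deep = wf.intensity[surf + 60 : surf + 70].mean()
        # expected decay over 550 um at 2/mm is ~exp(-1.1)
        assert deep < 0.6 * shallow

    def test_suture_bright_and_protruding(self, small_phantom):
        _, wf, truth = small_phantom
        assert truth.suture_mask.any()
        inside = truth.surface_depth_um[truth.suture_mask].mean()
        outside = truth.surface_depth_um[~truth.suture_mask].mean()
        assert inside < outside  # ridge raised above the surrounding surface

    def test_feature_outside_extent_rejected(self):
        with pytest.raises(ValidationError):
            _flat_spec(features=(TubularFeature("vessel", (0, 0), (99999, 0)),))

    def test_feature_rendered_with_mask(self):
        f = TubularFeature("vessel", (500.0, 1500.0), (2500.0, 1500.0), depth_um=300.0, radius_um=150.0)
        wf, truth = generate_shaving_phantom(_flat_spec(features=(f,), adipose_fraction=0.0))
        assert "vessel_0" in truth.feature_masks
        assert truth.feature_masks["vessel_0"].any()


class TestExtractTile:
    def test_identity_crop(self, small_phantom):
        _, wf, truth = small_phantom
        pose = RigidPose2D(3000.0, 3000.0, 0.0)
        tile = extract_tile(wf, truth, pose, tile_extent_um=3000.0)
        crop = wf.intensity[:, 50:150, 50:150]
        np.testing.assert_array_equal(tile.intensity, crop)

    def test_rotation_90_matches_rotated_crop(self, small_phantom):
        _, wf, truth = small_phantom
        straight = extract_tile(wf, truth, RigidPose2D(3000.0, 3000.0, 0.0), tile_extent_um=3000.0)
        rotated = extract_tile(wf, truth, RigidPose2D(3000.0, 3000.0, 90.0), tile_extent_um=3000.0)
        # +90 deg yaw maps the tile's +x axis onto +y: same voxels, re-indexed
        expect = np.stack([np.rot90(straight.intensity[z], k=1) for z in range(straight.nz)])
        np.testing.assert_allclose(rotated.intensity, expect, atol=1e-5)

    def test_out_of_bounds_rejected(self, small_phantom):
        _, wf, truth = small_phantom
        with pytest.raises(ValidationError, match="footprint"):
            extract_tile(wf, truth, RigidPose2D(500.0, 500.0, 0.0), tile_extent_um=3000.0)

    def test_noise_monotonically_degrades_similarity(self, small_phantom):
        _, wf, truth = small_phantom
        pose = RigidPose2D(3000.0, 3000.0, 0.0)
        clean = extract_tile(wf, truth, pose, tile_extent_um=3000.0).intensity
        nccs = []
        for sigma in [0.0, 0.05, 0.1, 0.2, 0.4]:
            noisy = extract_tile(wf, truth, pose, degrade=Degrade(noise_sigma=sigma), tile_extent_um=3000.0, seed=9).intensity
            a, b = clean.ravel(), noisy.ravel()
            ncc = np.corrcoef(a, b)[0, 1]
            nccs.append(ncc)
        assert all(x > y for x, y in zip(nccs, nccs[1:]))

    def test_tilt_shifts_sampled_depth_across_tile(self, small_phantom):
        _, wf, truth = small_phantom
        pose = RigidPose2D(3000.0, 3000.0, 0.0)
        tilted = extract_tile(wf, truth, pose, degrade=Degrade(tilt_deg=1.0), tile_extent_um=3000.0)
        straight = extract_tile(wf, truth, pose, tile_extent_um=3000.0)
        # the depth ramp grows from the tile centre outward: edge columns change
        # far more than the central one
        mid = tilted.intensity.shape[2] // 2
        d_mid = np.abs(tilted.intensity[:, :, mid] - straight.intensity[:, :, mid]).mean()
        d_edge = np.abs(tilted.intensity[:, :, 5] - straight.intensity[:, :, 5]).mean()
        assert d_edge > 5 * d_mid


class TestCompressionPair:
    def test_homogeneous_uniform_strain(self, flat_qme_phantom, linear_layer_curve):
        wf, truth = flat_qme_phantom
        pre, post, ct = simulate_compression_pair(
            wf, truth, linear_layer_curve, layer_thickness_um=300.0, actuation_um=25.0
        )
        # layer slope 20 kPa equals the 20 kPa sample: strain uniform everywhere
        # and equal to actuation / total thickness
        total_um = pre.nz * pre.spacing_z_um
        np.testing.assert_allclose(ct.strain, 25.0 / total_um, rtol=1e-9)

    def test_two_layer_series_strain_ratio(self, flat_qme_phantom, linear_layer_curve):
        wf, truth = flat_qme_phantom
        nz = wf.shape[0]
        e3 = np.full(wf.shape, 10.0)
        e3[: nz // 2] = 20.0  # E1 = 2 E2 -> equal stress, strain ratio 1:2
        _, _, ct = simulate_compression_pair(
            wf, truth, linear_layer_curve, layer_thickness_um=300.0, actuation_um=25.0, elasticity_3d=e3
        )
        nl = ct.n_layer
        top = ct.strain[nl + 2]
        bottom = ct.strain[nl + nz // 2 + 2]
        np.testing.assert_allclose(bottom / top, 2.0, rtol=1e-9)

    def test_boundary_condition_and_strain_integration(self, flat_qme_phantom, linear_layer_curve):
        wf, truth = flat_qme_phantom
        pre, post, ct = simulate_compression_pair(
            wf, truth, linear_layer_curve, layer_thickness_um=300.0, actuation_um=25.0
        )
        dz = pre.spacing_z_um
        # base displacement equals the actuation within 1%
        np.testing.assert_allclose(np.abs(ct.uz_um[-1]), 25.0, rtol=0.01)
        # independently integrating the strain reproduces the displacement field
        u_re = -np.cumsum(ct.strain, axis=0) * dz
        assert np.max(np.abs(u_re - ct.uz_um)) < 0.1 * dz

    def test_stress_constant_along_depth(self, flat_qme_phantom, linear_layer_curve):
        wf, truth = flat_qme_phantom
        _, _, ct = simulate_compression_pair(wf, truth, linear_layer_curve, layer_thickness_um=300.0, actuation_um=25.0)
        # E * strain must equal the layer stress at every sample voxel (series springs)
        prod = ct.strain[ct.n_layer :] * 20.0
        np.testing.assert_allclose(prod, np.broadcast_to(ct.stress_kPa, prod.shape), rtol=1e-9)

    def test_actuation_beyond_layer_range_rejected(self, flat_qme_phantom, linear_layer_curve):
        wf, truth = flat_qme_phantom
        with pytest.raises(ValidationError, match="actuation"):
            simulate_compression_pair(wf, truth, linear_layer_curve, layer_thickness_um=300.0, actuation_um=5000.0)

    def test_determinism(self, flat_qme_phantom, linear_layer_curve):
        wf, truth = flat_qme_phantom
        p1, q1, _ = simulate_compression_pair(wf, truth, linear_layer_curve, 300.0, 25.0, seed=5)
        p2, q2, _ = simulate_compression_pair(wf, truth, linear_layer_curve, 300.0, 25.0, seed=5)
        np.testing.assert_array_equal(p1.intensity, p2.intensity)
        np.testing.assert_array_equal(q1.intensity, q2.intensity)


class TestHistologySections:
    def test_section_count_matches_floor_rule(self, small_phantom):
        _, wf, truth = small_phantom
        # 9 mm specimen, 4.5 mm spacing, first line at half-spacing: 2 sections
        secs = generate_histology_sections(wf, truth, section_spacing_um=4500.0, shrink_factors=1.0)
        assert len(secs) == 2
        # 20 mm specimen / 5 mm spacing -> 4 sections (direct count oracle)
        positions = np.arange(2500.0, 20000.0, 5000.0)
        assert len(positions) == 4

    def test_identity_section_equals_bplane(self, small_phantom):
        _, wf, truth = small_phantom
        secs = generate_histology_sections(wf, truth, 4500.0, shrink_factors=1.0, warp_amplitude_um=0.0)
        sec = secs[0]
        y_idx = int(sec.line_y_um / wf.spacing_y_um)
        np.testing.assert_allclose(sec.image, wf.intensity[:, y_idx, :], atol=1e-6)

    def test_recorded_widths_encode_shrink_factor(self, small_phantom):
        _, wf, truth = small_phantom
        secs = generate_histology_sections(wf, truth, 4500.0, shrink_factors=[1.18, 1.25])
        for sec, c in zip(secs, [1.18, 1.25]):
            assert abs(sec.fresh_width_um / sec.section_width_um - c) < 1e-3

    def test_spacing_larger_than_specimen_rejected(self, small_phantom):
        _, wf, truth = small_phantom
        with pytest.raises(ValidationError):
            generate_histology_sections(wf, truth, section_spacing_um=50000.0)
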