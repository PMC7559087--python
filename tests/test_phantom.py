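import numpy as np
import pytest

from ocdvc import (
    DeformationModel,
    PhantomSpec,
    add_noise,
    generate_phantom,
    micromotion_model,
    warp_volume,
)
from ocdvc.volume import COMPONENT_NAMES


class TestGeneratePhantom:
    def test_seeded_determinism(self):
        spec = PhantomSpec(shape=(48, 48, 48), voxel_size_um=10.0, seed=7)
        a, _ = generate_phantom(spec)
        b, _ = generate_phantom(spec)
        np.testing.assert_array_equal(a.intensities, b.intensities)

    def test_legend_contains_all_component_names(self, small_phantom):
        _, mask = small_phantom
        assert set(mask.legend.values()) == set(COMPONENT_NAMES)

    def test_lattice_period_matches_strut_geometry(self):
        # 200 µm struts + 200 µm spacing -> 40-voxel period at 10 µm voxels,
        # the dominant spatial frequency of the implant intensity profile
        spec = PhantomSpec(shape=(128, 128, 128), voxel_size_um=10.0, seed=5, psf_sigma_um=0.0)
        vol, mask = generate_phantom(spec)
        period = spec.strut_period_vox
        assert period == round((200 + 200) / 10.0)
        imp = mask.labels == mask.label_of("implant")
        counts = imp.sum(axis=(0, 2))
        cols = counts > 0
        profile = np.where(imp, vol.intensities, 0.0).sum(axis=(0, 2))[cols] / counts[cols]
        p = profile - profile.mean()
        n = len(p)
        ac = np.array([np.mean(p[: n - k] * p[k:]) for k in range(n - 4)])
        lag = int(period * 0.6) + int(np.argmax(ac[int(period * 0.6) : int(period * 1.4)]))
        assert lag == pytest.approx(period, abs=1)

    def test_shape_too_small_for_one_strut_period(self):
        with pytest.raises(ValueError, match="strut period"):
            generate_phantom(PhantomSpec(shape=(16, 16, 16), voxel_size_um=10.0))

    def test_bone_texture_has_higher_contrast_than_void(self, small_phantom):
        from scipy import ndimage

        vol, mask = small_phantom
        bone = vol.intensities[mask.labels == mask.label_of("bone")]
        # interior void only: the blur mixes bright neighbours into its rim
        void_core = ndimage.binary_erosion(mask.labels == mask.label_of("void"))
        assert void_core.any()
        assert bone.std() > 3 * vol.intensities[void_core].std()


class TestWarpVolume:
    def test_zero_deformation_is_identity(self, small_phantom):
        vol, _ = small_phantom
        out, gt = warp_volume(vol, DeformationModel("translation", {"t_um": (0, 0, 0)}), 1)
        np.testing.assert_array_equal(out.intensities, vol.intensities)
        assert np.all(gt.displacement(np.zeros((2, 3))) == 0)

    def test_integer_translation_is_exact_shift(self, small_phantom):
        vol, _ = small_phantom
        out, _ = warp_volume(vol, DeformationModel("translation", {"t_um": (30, 0, 0)}), 1)
        # +3 voxels in x: interior content shifts exactly
        np.testing.assert_allclose(
            out.intensities[:, :, 3:], vol.intensities[:, :, :-3], atol=1e-9
        )

    def test_uniaxial_compression_analytic_field(self):
        model = DeformationModel(
            "uniaxial_compression",
            {"nominal_strain": 0.025, "poisson_ratio": 0.0, "fixed_z_um": 0.0},
        )
        gt = model.ground_truth()
        h = 640.0
        u = gt.displacement(np.array([[100.0, 100.0, h]]))
        assert u[0, 2] == pytest.approx(-0.025 * h)
        assert u[0, 0] == u[0, 1] == 0.0
        eps = gt.strain(np.array([[0.0, 0.0, 0.0], [50.0, 50.0, 300.0]]))
        np.testing.assert_allclose(eps[:, 2], -0.025)
        np.testing.assert_allclose(eps[:, [0, 1, 3, 4, 5]], 0.0)

    def test_rotation_ground_truth_is_rigid(self):
        model = DeformationModel(
            "rigid_rotation", {"axis": (0, 0, 1), "angle_deg": 1.0, "centre_um": (50, 50, 50)}
        )
        gt = model.ground_truth()
        pos = np.array([[80.0, 50.0, 50.0]])
        u = gt.displacement(pos)
        ang = np.deg2rad(1.0)
        assert u[0, 1] == pytest.approx(30 * np.sin(ang))
        assert u[0, 0] == pytest.approx(30 * (np.cos(ang) - 1))
        # infinitesimal strain of a rigid rotation is second-order small
        assert np.abs(gt.strain(pos)).max() < 2e-4

    def test_excessive_displacement_rejected(self, small_phantom):
        vol, _ = small_phantom  # extent 640 µm; cap is 25%
        with pytest.raises(ValueError, match="25%"):
            warp_volume(vol, DeformationModel("translation", {"t_um": (200.0, 0, 0)}), 1)

    def test_model_validation(self):
        with pytest.raises(ValueError):
            DeformationModel("uniaxial_compression", {"nominal_strain": 0.3})
        with pytest.raises(ValueError):
            DeformationModel("rigid_rotation", {"axis": (0, 0, 1), "angle_deg": 15.0})
        with pytest.raises(ValueError):
            DeformationModel("bogus", {})


class TestMicromotionModel:
    def test_rigid_interior_has_no_strain(self, small_phantom):
        vol, mask = small_phantom
        model = micromotion_model(0.025, 0.3, (0, 0, -40.0), mask, vol.voxel_size_um)
        gt = model.ground_truth()
        # centre of the implant: weight 1, strain vanishes, offset included
        zc, yc, xc = [s // 2 for s in mask.shape]
        assert mask.labels[int(0.45 * mask.shape[0]), yc, xc] == mask.label_of("implant")
        pos = np.array([[xc * 10.0, yc * 10.0, 0.45 * mask.shape[0] * 10.0]])
        eps = gt.strain(pos)
        assert np.abs(eps).max() < 2e-3
        u = gt.displacement(pos)
        assert u[0, 2] < -40.0  # rigid offset plus the frozen far-field motion

    def test_far_field_unaffected(self, small_phantom):
        vol, mask = small_phantom
        model = micromotion_model(0.025, 0.0, (0, 0, -40.0), mask, vol.voxel_size_um)
        gt = model.ground_truth()
        pos = np.array([[20.0, 20.0, 100.0]])  # bone corner, far from implant
        eps = gt.strain(pos)
        assert eps[0, 2] == pytest.approx(-0.025, abs=1e-4)


class TestAddNoise:
    def test_sigma_zero_is_identity(self, small_phantom):
        vol, _ = small_phantom
        out = add_noise(vol, 0.0, seed=1)
        np.testing.assert_array_equal(out.intensities, vol.intensities)

    def test_sample_sd_matches_sigma(self):
        from ocdvc import Volume3D

        vol = Volume3D(np.full((100, 100, 100), 50.0), 10.0)
        out = add_noise(vol, 2.5, seed=4)
        sd = (out.intensities - 50.0).std()
        assert sd == pytest.approx(2.5, rel=0.05)

    def test_different_seeds_same_mean(self):
        from ocdvc import Volume3D

        vol = Volume3D(np.full((64, 64, 64), 50.0), 10.0)
        a = add_noise(vol, 2.0, seed=1)
        b = add_noise(vol, 2.0, seed=2)
        assert not np.array_equal(a.intensities, b.intensities)
        assert a.intensities.mean() == pytest.approx(b.intensities.mean(), abs=0.05)

    def test_negative_sigma_rejected(self, small_phantom):
        vol, _ = small_phantom
        with pytest.raises(ValueError):
            add_noise(vol, -1.0, seed=0)
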