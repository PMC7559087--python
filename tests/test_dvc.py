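import numpy as np
import pytest
from skimage.feature import match_template

from ocdvc import (
    DeformationModel,
    DVCConfig,
    build_grid,
    correlate_dc,
    correlate_fft,
    correlate_multipass,
    ncc,
    subpixel_peak,
    warp_volume,
)
from ocdvc.dvc import zncc_search


class TestBuildGrid:
    def test_half_overlap_spacing(self):
        grid = build_grid((160, 160, 160), 80, 0.5)
        assert grid.step_vox == 40
        zs = np.unique(grid.starts[:, 0])
        assert np.all(np.diff(zs) == 40)

    def test_single_centre_when_subvolume_fills_volume(self):
        grid = build_grid((80, 80, 80), 80, 0.5)
        assert grid.n_points == 1

    def test_overflowing_second_subvolume_dropped(self):
        # 100-voxel axis fits one 80-voxel subvolume; the next would overflow
        grid = build_grid((100, 100, 100), 80, 0.5)
        assert grid.grid_shape == (1, 1, 1)

    def test_subvolume_larger_than_volume_rejected(self):
        with pytest.raises(ValueError):
            build_grid((64, 64, 64), 80, 0.5)

    def test_inset_keeps_subvolumes_off_faces(self):
        grid = build_grid((96, 96, 96), 32, 0.5, inset_vox=(8, 4, 4))
        assert grid.starts[:, 0].min() >= 8
        assert grid.starts[:, 1].min() >= 4
        assert (grid.starts[:, 0] + 32).max() <= 88

    def test_positions_at_geometric_centres(self):
        grid = build_grid((32, 32, 32), 16, 0.5, voxel_size_um=10.0)
        pos = grid.positions_um()
        assert pos[0].tolist() == [80.0, 80.0, 80.0]  # (0 + 16/2) * 10


class TestNCC:
    def test_identical_subvolumes(self):
        a = np.random.default_rng(0).random((8, 8, 8))
        assert ncc(a, a) == pytest.approx(1.0)

    def test_affine_intensity_invariance(self):
        a = np.random.default_rng(1).random((8, 8, 8))
        assert ncc(a, 3.0 * a + 7.0) == pytest.approx(1.0)

    def test_negated_subvolume(self):
        a = np.random.default_rng(2).random((8, 8, 8))
        assert ncc(a, -a) == pytest.approx(-1.0)

    def test_constant_subvolume_flags_invalid(self):
        a = np.random.default_rng(3).random((8, 8, 8))
        assert np.isnan(ncc(a, np.ones_like(a)))
        assert np.isnan(ncc(np.ones_like(a), a))

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            ncc(np.zeros((4, 4, 4)), np.zeros((5, 5, 5)))


class TestZNCCSearch:
    def test_matches_skimage_oracle(self):
        rng = np.random.default_rng(0)
        region = rng.random((20, 22, 24))
        template = region[3:13, 4:14, 5:15].copy()
        mine = zncc_search(region, template)
        ref = match_template(region, template)
        np.testing.assert_allclose(mine, ref, atol=1e-10)
        assert np.unravel_index(np.nanargmax(mine), mine.shape) == (3, 4, 5)

    def test_constant_template_is_nan(self):
        out = zncc_search(np.random.default_rng(1).random((12, 12, 12)), np.ones((8, 8, 8)))
        assert np.isnan(out).all()


class TestSubpixelPeak:
    def test_symmetric_profile_is_centred(self):
        assert subpixel_peak((0.5, 1.0, 0.5), "gaussian3").offset == pytest.approx(0.0)
        assert subpixel_peak((0.5, 1.0, 0.5), "parabolic3").offset == pytest.approx(0.0)

    def test_parabolic_closed_form(self):
        # vertex of the parabola through (-1, 0.6), (0, 1.0), (1, 0.4):
        # delta = (c- - c+) / (2 (c- - 2 c0 + c+)) = 0.2 / (2 * -1.0) = -0.1,
        # towards the larger neighbour
        res = subpixel_peak((0.6, 1.0, 0.4), "parabolic3")
        assert res.offset == pytest.approx(-0.1)
        assert not res.flagged

    def test_gaussian_closed_form(self):
        cm, c0, cp = 0.6, 1.0, 0.4
        expected = (np.log(cm) - np.log(cp)) / (
            2 * np.log(cm) - 4 * np.log(c0) + 2 * np.log(cp)
        )
        assert subpixel_peak((cm, c0, cp), "gaussian3").offset == pytest.approx(expected)
        assert expected < 0  # same sign convention as the parabolic fit

    def test_plateau_boundary_flagged(self):
        res = subpixel_peak((1.0, 1.0, 0.4), "gaussian3")
        assert res.offset == -0.5 and res.flagged

    def test_nonpositive_values_fall_back_to_parabolic(self):
        res = subpixel_peak((-0.2, 1.0, 0.1), "gaussian3")
        assert res.estimator == "parabolic3" and res.flagged

    def test_middle_must_dominate(self):
        with pytest.raises(ValueError):
            subpixel_peak((1.0, 0.5, 0.4))


def _interior(grid, shift_vox, shape):
    s = np.asarray(shift_vox)
    return np.all(grid.starts + s >= 0, axis=1) & np.all(
        grid.starts + s + grid.subvolume_size_vox <= np.array(shape), axis=1
    )


class TestCorrelators:
    def test_self_correlation_is_zero_field(self, medium_phantom, default_config):
        vol, _ = medium_phantom
        grid = build_grid(vol.shape, 32, 0.5, vol.voxel_size_um)
        fld = correlate_dc(vol, vol, grid, default_config)
        assert fld.valid.all()
        np.testing.assert_array_equal(fld.vectors_um, 0.0)
        np.testing.assert_allclose(fld.correlation, 1.0)

    def test_integer_shift_recovered_exactly_by_dc(self, medium_phantom, default_config):
        vol, _ = medium_phantom
        warped, _ = warp_volume(vol, DeformationModel("translation", {"t_um": (30, 20, 10)}), 1)
        grid = build_grid(vol.shape, 32, 0.5, vol.voxel_size_um)
        fld = correlate_dc(vol, warped, grid, default_config)
        interior = _interior(grid, (1, 2, 3), vol.shape)
        np.testing.assert_array_equal(
            fld.vectors_um[interior], np.tile([30.0, 20.0, 10.0], (interior.sum(), 1))
        )

    def test_fft_and_multipass_match_dc_oracle(self, sharp_phantom, default_config):
        vol, _ = sharp_phantom
        warped, _ = warp_volume(vol, DeformationModel("translation", {"t_um": (30, 20, 10)}), 1)
        grid = build_grid(vol.shape, 32, 0.5, vol.voxel_size_um)
        dc = correlate_dc(vol, warped, grid, default_config)
        fft = correlate_fft(vol, warped, grid, default_config)
        mp = correlate_multipass(vol, warped, grid, default_config)
        interior = _interior(grid, (1, 2, 3), vol.shape)
        assert (fft.valid & interior).sum() == interior.sum()
        np.testing.assert_array_equal(fft.vectors_um[interior], dc.vectors_um[interior])
        np.testing.assert_array_equal(mp.vectors_um[interior], dc.vectors_um[interior])

    def test_subvoxel_shift_recovered_within_tenth_voxel(self, medium_phantom, default_config):
        vol, mask = medium_phantom
        vs = vol.voxel_size_um
        warped, _ = warp_volume(
            vol, DeformationModel("translation", {"t_um": (0.5 * vs, 0, 0)}), 3
        )
        grid = build_grid(vol.shape, 32, 0.5, vs)
        fld = correlate_dc(vol, warped, grid, default_config)
        # subvolumes must keep the full two-sided search radius inside the
        # volume: a clipped (one-sided) search cannot bracket the peak
        margin = default_config.dc_search_radius_vox + 1
        interior = (grid.starts[:, 2] >= margin) & (
            grid.starts[:, 2] + 32 + margin <= vol.shape[2]
        )
        # well-textured (bone) subvolumes; texture-poor pores cannot resolve
        # subvoxel motion and are judged by the low-correlation flag instead
        lab = mask.labels[grid.centres[:, 0], grid.centres[:, 1], grid.centres[:, 2]]
        sel = interior & (lab == mask.label_of("bone")) & (fld.correlation >= 0.9)
        assert sel.sum() > 20
        err = np.abs(fld.vectors_um[sel, 0] - 0.5 * vs)
        assert err.max() < 0.1 * vs

    def test_fft_flags_wrap_ambiguous_shift(self, sharp_phantom, default_config):
        from ocdvc import Volume3D

        vol, _ = sharp_phantom
        vs = vol.voxel_size_um
        # half the subvolume edge under the cyclic convention: the peak
        # aliases between +16 and -16 and must be flagged, not reported
        rolled = Volume3D(np.roll(vol.intensities, 16, axis=2), vs)
        grid = build_grid(vol.shape, 32, 0.5, vs)
        fld = correlate_fft(vol, rolled, grid, default_config)
        assert not fld.valid.any()

    def test_multipass_tracks_shift_beyond_dc_radius(self, medium_phantom):
        vol, _ = medium_phantom
        vs = vol.voxel_size_um
        warped, _ = warp_volume(
            vol, DeformationModel("translation", {"t_um": (0, 0, 10.25 * vs)}), 3
        )
        cfg = DVCConfig(dc_search_radius_vox=5)
        grid = build_grid(vol.shape, 32, 0.5, vs, inset_vox=(12, 0, 0))
        fld = correlate_multipass(vol, warped, grid, cfg)
        interior = _interior(grid, (11, 0, 0), vol.shape)
        err = np.abs(fld.vectors_um[interior & fld.valid, 2] - 10.25 * vs)
        assert np.median(err) < 0.1 * vs

    def test_intensity_affine_change_leaves_field_unchanged(
        self, medium_phantom, default_config
    ):
        from ocdvc import Volume3D

        vol, _ = medium_phantom
        warped, _ = warp_volume(vol, DeformationModel("translation", {"t_um": (30, 0, 0)}), 1)
        bright = Volume3D(1.7 * warped.intensities + 25.0, vol.voxel_size_um)
        grid = build_grid(vol.shape, 32, 0.5, vol.voxel_size_um)
        a = correlate_dc(vol, warped, grid, default_config)
        b = correlate_dc(vol, bright, grid, default_config)
        np.testing.assert_allclose(a.vectors_um, b.vectors_um, atol=1e-9)

    def test_swap_symmetry_negates_vectors(self, medium_phantom, default_config):
        vol, mask = medium_phantom
        vs = vol.voxel_size_um
        warped, _ = warp_volume(
            vol, DeformationModel("translation", {"t_um": (0.3 * vs, 0, 0)}), 3
        )
        grid = build_grid(vol.shape, 32, 0.5, vs, inset_vox=(4, 4, 4))
        fwd = correlate_dc(vol, warped, grid, default_config)
        bwd = correlate_dc(warped, vol, grid, default_config)
        lab = mask.labels[grid.centres[:, 0], grid.centres[:, 1], grid.centres[:, 2]]
        both = (
            fwd.valid
            & bwd.valid
            & (lab == mask.label_of("bone"))
            & (fwd.correlation >= 0.9)
            & (bwd.correlation >= 0.9)
        )
        assert both.sum() > 25
        # aggregate symmetry: individual sharp-texture points carry
        # interpolation bias of either sign that exceeds the subpixel noise
        asym = np.abs(fwd.vectors_um[both] + bwd.vectors_um[both])
        assert np.median(asym, axis=0).max() < 0.05 * vs
        assert np.abs(fwd.vectors_um[both].mean(axis=0) + bwd.vectors_um[both].mean(axis=0)).max() < 0.05 * vs

    def test_textureless_subvolumes_flagged_not_spurious(self, default_config):
        from ocdvc import Volume3D

        rng = np.random.default_rng(9)
        data = np.full((64, 64, 64), 100.0)
        data[:, :, 32:] += rng.normal(0, 10, size=(64, 64, 32))  # texture on one side
        vol = Volume3D(data, 10.0)
        grid = build_grid(vol.shape, 16, 0.5, 10.0)
        fld = correlate_dc(vol, vol, grid, default_config)
        flat = grid.centres[:, 2] < 24
        assert not fld.valid[flat].any()
        assert fld.valid[~flat & (grid.centres[:, 2] > 40)].all()
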