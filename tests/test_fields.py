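import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ocdvc import (
    RigidTransform,
    compute_strain,
    fit_rigid_body,
    principal_strains,
    subtract_rigid,
    total_displacement,
)


def rotation_field(angle_deg, centre_um):
    ang = np.deg2rad(angle_deg)
    R = np.array(
        [[np.cos(ang), -np.sin(ang), 0.0], [np.sin(ang), np.cos(ang), 0.0], [0.0, 0.0, 1.0]]
    )
    c = np.asarray(centre_um)
    return lambda pos: (pos - c) @ (R.T - np.eye(3)), R


class TestRigidFit:
    def test_constant_field_is_pure_translation(self, uniform_field):
        fld = uniform_field((3.0, -2.0, 1.0))
        tf = fit_rigid_body(fld)
        np.testing.assert_allclose(tf.rotation, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(tf.translation_um, [3.0, -2.0, 1.0], atol=1e-12)
        assert tf.residual_rms_um < 1e-9

    def test_one_degree_rotation_recovered(self, analytic_field):
        fn, R = rotation_field(1.0, (320.0, 320.0, 320.0))
        fld = analytic_field(fn)
        tf = fit_rigid_body(fld)
        recovered = np.degrees(np.arctan2(tf.rotation[1, 0], tf.rotation[0, 0]))
        assert recovered == pytest.approx(1.0, abs=0.01)

    def test_zero_field_is_identity(self, uniform_field):
        tf = fit_rigid_body(uniform_field((0, 0, 0)))
        np.testing.assert_allclose(tf.rotation, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(tf.translation_um, 0.0, atol=1e-12)

    def test_too_few_valid_points_raise(self, uniform_field):
        fld = uniform_field((1, 1, 1))
        fld.valid[:] = False
        fld.valid[:2] = True
        with pytest.raises(ValueError):
            fit_rigid_body(fld)


class TestSubtractRigid:
    def test_annihilates_own_fit(self, analytic_field):
        fn, _ = rotation_field(0.5, (100.0, 200.0, 300.0))
        fld = analytic_field(lambda p: fn(p) + np.array([5.0, -3.0, 2.0]))
        residual = subtract_rigid(fld, fit_rigid_body(fld))
        rms = np.sqrt((residual.vectors_um**2).sum(axis=1).mean())
        assert rms < 1e-6

    def test_identity_transform_leaves_field(self, uniform_field):
        fld = uniform_field((1.0, 2.0, 3.0))
        out = subtract_rigid(fld, RigidTransform.identity())
        np.testing.assert_allclose(out.vectors_um, fld.vectors_um)

    def test_rigid_plus_elongation_leaves_elongation(self, analytic_field):
        t = np.array([4.0, 0.0, -1.0])
        fld = analytic_field(
            lambda p: np.column_stack([np.zeros(len(p)), np.zeros(len(p)), 0.01 * p[:, 2]])
            + t
        )
        residual = subtract_rigid(fld, fit_rigid_body(fld))
        pos = fld.grid.positions_um()
        expected = 0.01 * (pos[:, 2] - pos[:, 2].mean())
        np.testing.assert_allclose(residual.vectors_um[:, 2], expected, atol=1e-9)
        np.testing.assert_allclose(residual.vectors_um[:, :2], 0.0, atol=1e-9)


class TestComputeStrain:
    def test_uniform_field_has_zero_strain(self, uniform_field):
        strain = compute_strain(uniform_field((5.0, 5.0, 5.0)), window=3)
        assert strain.valid.all()
        np.testing.assert_allclose(strain.components, 0.0, atol=1e-12)

    def test_linear_uz_gives_exact_ezz(self, analytic_field):
        fld = analytic_field(
            lambda p: np.column_stack(
                [np.zeros(len(p)), np.zeros(len(p)), -0.025 * p[:, 2]]
            )
        )
        strain = compute_strain(fld, window=3)
        np.testing.assert_allclose(strain.components[strain.valid, 2], -0.025, atol=1e-12)

    def test_pure_shear_hand_check(self, analytic_field):
        # u_x = 0.01 y, u_y = 0.01 x -> eps_xy = 0.01, no rotation part
        fld = analytic_field(
            lambda p: np.column_stack([0.01 * p[:, 1], 0.01 * p[:, 0], np.zeros(len(p))])
        )
        strain = compute_strain(fld, window=3)
        np.testing.assert_allclose(strain.components[strain.valid, 3], 0.01, atol=1e-12)
        np.testing.assert_allclose(
            strain.components[strain.valid][:, [0, 1, 2, 4, 5]], 0.0, atol=1e-12
        )

    @pytest.mark.parametrize("window", [3, 5])
    def test_affine_exact_for_any_window(self, analytic_field, window):
        H = np.array([[0.01, 0.002, 0.0], [0.002, -0.005, 0.001], [0.0, 0.001, -0.02]])
        fld = analytic_field(lambda p: p @ H.T)
        strain = compute_strain(fld, window=window)
        E = 0.5 * (H + H.T)
        expected = [E[0, 0], E[1, 1], E[2, 2], E[0, 1], E[0, 2], E[1, 2]]
        np.testing.assert_allclose(
            strain.components[strain.valid], np.tile(expected, (strain.valid.sum(), 1)),
            atol=1e-12,
        )

    def test_strain_objectivity_under_constant_offset(self, analytic_field):
        base = lambda p: np.column_stack([0.01 * p[:, 2], -0.02 * p[:, 0], 0.005 * p[:, 1]])
        a = compute_strain(analytic_field(base), window=3)
        b = compute_strain(analytic_field(lambda p: base(p) + 17.0), window=3)
        np.testing.assert_allclose(a.components, b.components, atol=1e-10)

    def test_invalid_inputs(self, uniform_field):
        with pytest.raises(ValueError):
            compute_strain(uniform_field((0, 0, 0)), window=4)
        single = uniform_field((0, 0, 0), shape=(16, 16, 16), size=16)
        with pytest.raises(ValueError):
            compute_strain(single, window=3)


class TestPrincipalStrains:
    def test_diagonal_tensor_sorted_ascending(self):
        vals = principal_strains([-0.025, 0.01, 0.005, 0.0, 0.0, 0.0])
        np.testing.assert_allclose(vals, [-0.025, 0.005, 0.01])

    def test_pure_shear_closed_form(self):
        vals = principal_strains([0.0, 0.0, 0.0, 0.01, 0.0, 0.0])
        np.testing.assert_allclose(vals, [-0.01, 0.0, 0.01], atol=1e-15)

    def test_zero_tensor(self):
        np.testing.assert_array_equal(principal_strains([0.0] * 6), [0.0, 0.0, 0.0])

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            principal_strains([np.nan, 0, 0, 0, 0, 0])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-0.05, 0.05), min_size=6, max_size=6), st.integers(0, 10**6))
    def test_invariant_under_frame_rotation(self, comps, seed):
        # conjugating the tensor by a rotation must not change its eigenvalues
        exx, eyy, ezz, exy, exz, eyz = comps
        T = np.array([[exx, exy, exz], [exy, eyy, eyz], [exz, eyz, ezz]])
        rng = np.random.default_rng(seed)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        Tr = q @ T @ q.T
        rotated = [Tr[0, 0], Tr[1, 1], Tr[2, 2], Tr[0, 1], Tr[0, 2], Tr[1, 2]]
        np.testing.assert_allclose(
            principal_strains(comps), principal_strains(rotated), atol=1e-10
        )


class TestTotalDisplacement:
    def test_norms(self, uniform_field):
        fld = uniform_field((3.0, 4.0, 0.0))
        np.testing.assert_allclose(total_displacement(fld), 5.0)
        np.testing.assert_allclose(
            total_displacement(uniform_field((1.0, 1.0, 1.0))), np.sqrt(3)
        )
        np.testing.assert_allclose(total_displacement(uniform_field((0, 0, 0))), 0.0)
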