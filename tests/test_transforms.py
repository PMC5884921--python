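"""Transform algebra, warping, resampling and landmark mapping."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import ndimage

from serialrecon.transforms import (
    apply_rigid_2d,
    compose_rigid_2d,
    image_center_mm,
    invert_displacement_field,
    resample_volume,
    transform_landmarks,
    warp_with_field,
)
from serialrecon.types import (
    AffineTransform3D,
    DisplacementField,
    LandmarkSet,
    RigidTransform2D,
    Volume3D,
)

PS = 0.04


def small_rigids():
    return st.builds(
        RigidTransform2D,
        theta=st.floats(-1.0, 1.0),
        t=st.tuples(st.floats(-2, 2), st.floats(-2, 2)).map(np.array),
        center=st.just(np.array([0.5, 0.7])),
    )


class TestRigid2D:
    def test_identity_leaves_image_unchanged(self, blob_image):
        T = RigidTransform2D.identity(image_center_mm(blob_image.shape, PS))
        out = apply_rigid_2d(blob_image, T, PS)
        np.testing.assert_allclose(out, blob_image, atol=1e-12)

    def test_translation_moves_spike_exactly(self):
        img = np.zeros((32, 32))
        img[10, 20] = 1.0
        T = RigidTransform2D(0.0, np.array([2 * PS, 0.0]), np.zeros(2))
        out = apply_rigid_2d(img, T, PS)
        assert out[12, 20] == pytest.approx(1.0)
        assert out[10, 20] == 0.0

    def test_rotation_round_trip_small_error(self):
        rng = np.random.default_rng(0)
        n = 64
        yy, xx = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        blob = np.exp(-0.5 * (np.hypot(yy - 32, xx - 32) / 12) ** 2)
        tex = ndimage.gaussian_filter(rng.standard_normal((n, n)), 4.0)
        img = blob * (1 + 0.3 * tex / tex.std())
        center = image_center_mm(img.shape, PS)
        theta = np.radians(17.0)
        fwd = apply_rigid_2d(img, RigidTransform2D(theta, np.zeros(2), center), PS)
        back = apply_rigid_2d(fwd, RigidTransform2D(-theta, np.zeros(2), center), PS)
        # interior only: the frame corners leave the domain under rotation
        sl = slice(8, -8)
        err = np.abs(back[sl, sl] - img[sl, sl]).max()
        assert err < 0.02 * np.ptp(img)

    def test_compose_with_inverse_is_identity(self):
        T = RigidTransform2D(0.3, np.array([1.0, -2.0]), np.array([0.5, 0.5]))
        I = compose_rigid_2d(T, T.inverse())
        assert abs(I.theta) < 1e-12
        np.testing.assert_allclose(I.t, 0.0, atol=1e-12)

    def test_compose_two_translations(self):
        A = RigidTransform2D(0.0, np.array([1.0, 0.0]), np.zeros(2))
        B = RigidTransform2D(0.0, np.array([0.0, 2.0]), np.zeros(2))
        C = compose_rigid_2d(A, B)
        np.testing.assert_allclose(C.t, [1.0, 2.0])
        assert C.theta == 0.0

    def test_compose_matches_homogeneous_matrix_product(self):
        A = RigidTransform2D(np.pi / 2, np.array([1.0, 0.0]), np.zeros(2))
        B = RigidTransform2D(0.2, np.array([0.3, -0.4]), np.zeros(2))
        C = compose_rigid_2d(A, B)
        np.testing.assert_allclose(C.matrix(), A.matrix() @ B.matrix(), atol=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(small_rigids(), small_rigids(), small_rigids())
    def test_composition_associative(self, A, B, C):
        left = compose_rigid_2d(compose_rigid_2d(A, B), C)
        right = compose_rigid_2d(A, compose_rigid_2d(B, C))
        np.testing.assert_allclose(left.matrix(), right.matrix(), atol=1e-9)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(small_rigids())
    def test_double_inverse_returns_original(self, T):
        TT = T.inverse().inverse()
        assert abs(TT.theta - T.theta) < 1e-10
        np.testing.assert_allclose(TT.t, T.t, atol=1e-10)

    def test_resampling_matches_simpleitk_reference(self, blob_image):
        # independent reference implementation: the same rigid resampling
        # through SimpleITK's Euler2DTransform must agree to float
        # precision wherever the source sample lies inside the image
        # (edge semantics differ: ITK zeroes beyond the pixel-center hull)
        sitk = pytest.importorskip("SimpleITK")
        center = image_center_mm(blob_image.shape, PS)
        T = RigidTransform2D(np.radians(9.0), np.array([0.1, -0.06]), center)
        ours = apply_rigid_2d(blob_image, T, PS)

        itk_img = sitk.GetImageFromArray(blob_image)
        itk_img.SetSpacing((PS, PS))
        inv = T.inverse()
        tf = sitk.Euler2DTransform()
        tf.SetCenter((center[1], center[0]))  # ITK x = our second index
        tf.SetAngle(-inv.theta)  # axis swap flips the rotation sense
        tf.SetTranslation((inv.t[1], inv.t[0]))
        theirs = sitk.GetArrayFromImage(
            sitk.Resample(itk_img, itk_img, tf, sitk.sitkLinear, 0.0)
        )

        n = blob_image.shape[0]
        grid = np.stack(
            np.meshgrid(np.arange(n), np.arange(n), indexing="ij"), axis=-1
        ).reshape(-1, 2)
        src = inv.apply_points(grid * PS) / PS
        inside = np.all((src >= 1.0) & (src <= n - 2.0), axis=1).reshape(n, n)
        assert np.abs(ours - theirs)[inside].max() < 1e-9

    def test_nonfinite_transform_rejected(self):
        with pytest.raises(ValueError):
            RigidTransform2D(np.nan, np.zeros(2), np.zeros(2))


class TestFields:
    def test_zero_field_is_identity(self, blob_image):
        f = DisplacementField.zero(blob_image.shape, [PS, PS])
        np.testing.assert_allclose(warp_with_field(blob_image, f), blob_image)

    def test_constant_field_is_pure_shift(self):
        img = np.zeros((32, 32))
        img[16, 16] = 1.0
        vec = np.zeros((32, 32, 2))
        vec[..., 0] = 2 * PS  # sample at x + 2 voxels
        out = warp_with_field(img, DisplacementField(vec, [PS, PS]))
        assert out[14, 16] == pytest.approx(1.0)

    def test_field_inversion_round_trip(self):
        rng = np.random.default_rng(1)
        vec = np.stack(
            [ndimage.gaussian_filter(rng.standard_normal((48, 48)), 6.0) for _ in range(2)],
            axis=-1,
        )
        vec *= (1.5 * PS) / np.sqrt((vec**2).sum(-1)).mean()
        f = DisplacementField(vec, [PS, PS])
        inv = invert_displacement_field(f)
        # composite residual: x -> x + inv(x) + f(x + inv(x)) should be x
        grids = np.meshgrid(np.arange(48.0), np.arange(48.0), indexing="ij")
        pts = np.stack([g * PS for g in grids], axis=-1)
        from serialrecon.transforms import _sample_field_mm

        moved = pts + inv.vectors
        resid = moved + _sample_field_mm(f, moved.reshape(-1, 2)).reshape(moved.shape) - pts
        interior = (slice(4, -4), slice(4, -4))
        assert np.abs(resid[interior]).max() / PS < 0.25

    def test_grid_mismatch_rejected(self, blob_image):
        f = DisplacementField.zero((16, 16), [PS, PS])
        with pytest.raises(ValueError):
            warp_with_field(blob_image, f)


class TestResample:
    def test_same_spacing_preserves_grid(self):
        v = Volume3D(np.random.default_rng(0).random((8, 9, 10)), 0.04)
        out = resample_volume(v, 0.04)
        assert out.shape == v.shape
        np.testing.assert_allclose(out.values, v.values)

    def test_constant_volume_stays_constant(self):
        v = Volume3D(np.full((10, 10, 10), 3.5), 0.05)
        out = resample_volume(v, 0.02)
        np.testing.assert_allclose(out.values, 3.5)

    def test_blockface_stack_to_isotropic_shape(self):
        # blockface-like geometry: fine in-plane pixels, 40 um cut thickness,
        # resampled to 40 um isotropic; shape must match the world extent
        v = Volume3D(np.zeros((100, 30, 120)), [0.0169, 0.040, 0.0169])
        out = resample_volume(v, 0.040)
        expected = np.round(v.extent_mm() / 0.040)
        assert np.all(np.abs(np.array(out.shape) - expected) <= 1)

    def test_linear_interpolation_does_not_expand_range(self):
        rng = np.random.default_rng(2)
        v = Volume3D(rng.random((12, 12, 12)), 0.04)
        out = resample_volume(v, 0.03)
        assert out.values.min() >= v.values.min() - 1e-12
        assert out.values.max() <= v.values.max() + 1e-12

    def test_down_up_round_trip_smooth_volume(self):
        rng = np.random.default_rng(3)
        vals = ndimage.gaussian_filter(rng.standard_normal((32, 32, 32)), 3.0)
        v = Volume3D(vals, 0.04)
        down = resample_volume(v, 0.08)
        up = resample_volume(down, 0.04)
        rms = np.sqrt(np.mean((up.values - v.values) ** 2))
        assert rms < 0.05 * np.ptp(v.values)

    def test_nonpositive_spacing_rejected(self):
        v = Volume3D(np.zeros((4, 4, 4)), 0.04)
        with pytest.raises(ValueError):
            resample_volume(v, -0.01)


class TestTransformLandmarks:
    def test_identity_affine_unchanged(self):
        lm = LandmarkSet.from_points([[1, 2, 3], [0.5, 0.5, 0.5]])
        out = transform_landmarks(lm, AffineTransform3D.identity())
        np.testing.assert_allclose(out.coords, lm.coords)
        assert out.names == lm.names

    def test_pure_translation_shifts_every_point(self):
        lm = LandmarkSet.from_points([[1, 2, 3], [4, 5, 6]])
        T = AffineTransform3D(np.eye(3), np.array([1.0, 2.0, 3.0]))
        out = transform_landmarks(lm, T)
        np.testing.assert_allclose(out.coords, lm.coords + [1, 2, 3])

    def test_field_moves_points_with_image_features(self):
        # oracle: a point must land where the warped impulse's centroid lands
        rng = np.random.default_rng(4)
        n = 48
        vec = np.stack(
            [ndimage.gaussian_filter(rng.standard_normal((n, n, n)), 7.0) for _ in range(3)],
            axis=-1,
        )
        vec *= (1.5 * PS) / np.sqrt((vec**2).sum(-1)).mean()
        field = DisplacementField(vec, [PS] * 3)
        p = np.array([24, 22, 26]) * PS
        lm = LandmarkSet(["p"], p[None, :])
        moved = transform_landmarks(lm, field).coords[0]

        impulse = np.zeros((n, n, n))
        impulse[24, 22, 26] = 1.0
        smooth = ndimage.gaussian_filter(impulse, 1.5)
        warped = warp_with_field(smooth, field)
        idx = np.array(
            ndimage.center_of_mass(warped)
        ) * PS
        assert np.linalg.norm(moved - idx) / PS < 0.25

    def test_offgrid_landmark_flagged_not_dropped(self):
        field = DisplacementField.zero((8, 8), [PS, PS])
        lm = LandmarkSet(["inside", "outside"], np.array([[0.1, 0.1, 0.0], [5.0, 5.0, 0.0]]))
        out = transform_landmarks(lm, field)
        assert len(out) == 2
        assert out.names[0] == "inside"
        assert out.names[1].endswith("!offgrid")
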