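"""Rigid reconstruction: registration, propagation, coarse/fine, merge."""

import numpy as np
import pytest
from scipy import ndimage

from serialrecon.phantom import PhantomSpec, section_phantom
from serialrecon.rigid import (
    TransformSeries,
    align_blockface_stack,
    apply_transform_series,
    coarse_align_to_blockface,
    coarse_to_fine_transforms,
    fine_sequential_align,
    merge_coarse_fine,
    reconstruct_rigid_volume,
    register_rigid_2d,
)
from serialrecon.stereotax import rod_centroids_from_volume, rod_straightness
from serialrecon.transforms import apply_rigid_2d, compose_rigid_2d, image_center_mm
from serialrecon.types import RigidTransform2D

PS = 0.04


def measured_tilt(volume):
    return rod_straightness(rod_centroids_from_volume(volume))["tilt_deg"]


class TestRegisterRigid2D:
    def test_identical_images_identity(self, blob_image):
        T, value = register_rigid_2d(blob_image, blob_image, PS)
        assert np.linalg.norm(T.t) / PS < 0.1
        assert abs(np.degrees(T.theta)) < 0.05
        assert value > 0.99

    def test_known_shift_recovered(self, blob_image):
        center = image_center_mm(blob_image.shape, PS)
        T_true = RigidTransform2D(0.0, np.array([3 * PS, -2 * PS]), center)
        moved = apply_rigid_2d(blob_image, T_true, PS)
        T, _ = register_rigid_2d(moved, blob_image, PS)
        # T must undo the shift
        np.testing.assert_allclose(T.t / PS, [-3, 2], atol=0.25)

    def test_known_rotation_recovered(self, blob_image):
        center = image_center_mm(blob_image.shape, PS)
        moved = apply_rigid_2d(blob_image, RigidTransform2D(np.radians(5), np.zeros(2), center), PS)
        T, _ = register_rigid_2d(moved, blob_image, PS)
        assert abs(np.degrees(T.theta) + 5.0) < 0.25

    def test_swap_gives_inverse(self, blob_image):
        center = image_center_mm(blob_image.shape, PS)
        T_true = RigidTransform2D(np.radians(4), np.array([2 * PS, PS]), center)
        moved = apply_rigid_2d(blob_image, T_true, PS)
        fwd, _ = register_rigid_2d(moved, blob_image, PS)
        bwd, _ = register_rigid_2d(blob_image, moved, PS)
        comp = compose_rigid_2d(fwd, bwd)
        assert np.linalg.norm(comp.t) / PS < 0.3
        assert abs(np.degrees(comp.theta)) < 0.3

    def test_contrastless_image_rejected(self, blob_image):
        with pytest.raises(ValueError):
            register_rigid_2d(np.zeros_like(blob_image), blob_image, PS)


class TestBlockfaceAlignment:
    def test_zero_jitter_all_identity(self):
        spec = PhantomSpec(
            grid_shape=(48, 32, 48), seed=2, damaged_fraction=0.0,
            blockface_jitter_trans=0.0, blockface_jitter_rot=0.0,
        )
        blockface, _, _ = section_phantom(spec)
        series = align_blockface_stack(blockface, ref_index=len(blockface) // 2)
        for T in series.transforms:
            assert np.linalg.norm(T.t) / PS < 0.1
            assert abs(np.degrees(T.theta)) < 0.05

    def test_jittered_stack_recovered_vs_truth(self, jittered_phantom):
        spec, blockface, _, truth = jittered_phantom
        ref = len(blockface) // 2
        series = align_blockface_stack(blockface, ref_index=ref)
        errs_t, errs_r = [], []
        for i, A in enumerate(series.transforms):
            expected = compose_rigid_2d(
                truth.blockface_rigid[ref], truth.blockface_rigid[i].inverse()
            )
            errs_t.append(np.linalg.norm(A.t - expected.t) / spec.spacing)
            errs_r.append(np.degrees(abs(A.theta - expected.theta)))
        assert np.sqrt(np.mean(np.square(errs_t))) < 0.5
        assert np.sqrt(np.mean(np.square(errs_r))) < 0.5

    def test_reference_transform_is_identity(self, jittered_phantom):
        _, blockface, _, _ = jittered_phantom
        ref = 3
        series = align_blockface_stack(blockface, ref_index=ref)
        assert np.linalg.norm(series.transforms[ref].t) == 0.0
        assert series.transforms[ref].theta == 0.0


class TestCoarseAlign:
    def test_parity_series_address_disjoint_blockface_indices(self, small_phantom):
        _, _, stained, _ = small_phantom
        a = {stained["nissl"].physical_index(i) for i in range(len(stained["nissl"]))}
        b = {stained["myelin"].physical_index(i) for i in range(len(stained["myelin"]))}
        assert a.isdisjoint(b)

    def test_blockface_to_itself_identity(self, small_phantom):
        _, blockface, _, _ = small_phantom
        sub = blockface.copy()
        coarse = coarse_align_to_blockface(sub, blockface)
        for T in coarse.transforms:
            assert np.linalg.norm(T.t) / PS < 0.1
            assert abs(np.degrees(T.theta)) < 0.1

    def test_out_of_range_rejected(self, small_phantom):
        from serialrecon.types import SectionSeries

        _, blockface, stained, _ = small_phantom
        too_many = SectionSeries(
            [s.copy() for s in stained["nissl"].sections] * 3,
            stained["nissl"].pixel_size,
            interleave=2,
            parity=0,
        )
        with pytest.raises(ValueError):
            coarse_align_to_blockface(too_many, blockface)


class TestMergeCoarseFine:
    def _series(self, params, center):
        return TransformSeries(
            [RigidTransform2D(p[0], np.array(p[1:]), center.copy()) for p in params]
        )

    def test_constant_fine_returns_coarse_exactly(self):
        center = np.array([1.0, 1.0])
        rng = np.random.default_rng(0)
        coarse = self._series(rng.normal(0, 0.05, size=(20, 3)), center)
        fine = self._series(np.tile([0.02, 0.3, -0.1], (20, 1)), center)
        merged = merge_coarse_fine(coarse, fine, sigma_sections=5.0)
        np.testing.assert_allclose(merged.parameters(), coarse.parameters(), atol=1e-12)

    def test_sigma_zero_returns_coarse_exactly(self):
        center = np.zeros(2)
        rng = np.random.default_rng(1)
        coarse = self._series(rng.normal(0, 0.05, size=(15, 3)), center)
        fine = self._series(rng.normal(0, 0.05, size=(15, 3)), center)
        merged = merge_coarse_fine(coarse, fine, sigma_sections=0.0)
        np.testing.assert_allclose(merged.parameters(), coarse.parameters(), atol=1e-12)

    def test_sinusoid_retention_matches_gaussian_frequency_response(self):
        # closed form: a period-T sinusoid survives the high-pass with
        # amplitude factor 1 - exp(-2 pi^2 sigma^2 / T^2)
        n, T_period, sigma = 64, 4.0, 5.0
        center = np.zeros(2)
        i = np.arange(n)
        tx = 0.5 * np.sin(2 * np.pi * i / T_period)
        coarse = self._series(np.zeros((n, 3)), center)
        fine = self._series(np.stack([np.zeros(n), tx, np.zeros(n)], axis=1), center)
        merged = merge_coarse_fine(coarse, fine, sigma_sections=sigma)
        out = merged.parameters()[:, 1]
        # projection on the sinusoid over the interior (boundary-free) part
        sl = slice(16, 48)
        basis = np.sin(2 * np.pi * i[sl] / T_period)
        amp_frac = (out[sl] @ basis) / (tx[sl] @ basis)
        expected = 1.0 - np.exp(-2 * np.pi**2 * sigma**2 / T_period**2)
        assert amp_frac == pytest.approx(expected, abs=0.01)
        assert amp_frac >= 0.99

    def test_length_mismatch_rejected(self):
        center = np.zeros(2)
        a = self._series(np.zeros((5, 3)), center)
        b = self._series(np.zeros((6, 3)), center)
        with pytest.raises(ValueError):
            merge_coarse_fine(a, b)


@pytest.fixture(scope="module")
def reconstruction():
    spec = PhantomSpec(grid_shape=(64, 96, 64), damaged_fraction=0.0, seed=2)
    blockface, stained, truth = section_phantom(spec)
    series = stained["myelin"]
    bf_t = align_blockface_stack(blockface, ref_index=len(blockface) // 2)
    bf_aligned = apply_transform_series(blockface, bf_t)
    coarse = coarse_align_to_blockface(series, bf_aligned)
    fine = fine_sequential_align(series, center_index=len(series) // 2)
    merged = coarse_to_fine_transforms(coarse, fine, sigma_sections=5.0)
    return spec, series, truth, fine, merged


class TestBananaEffect:
    def test_fine_only_straightens_oblique_rod(self, reconstruction):
        spec, series, _, fine, _ = reconstruction
        tilt = measured_tilt(reconstruct_rigid_volume(series, fine))
        assert tilt < 0.5 * spec.true_rod_tilt_deg()

    def test_merged_preserves_rod_tilt(self, reconstruction):
        spec, series, _, _, merged = reconstruction
        tilt = measured_tilt(reconstruct_rigid_volume(series, merged))
        true_tilt = spec.true_rod_tilt_deg()
        assert abs(tilt - true_tilt) < 0.1 * true_tilt

    def test_mask_volume_preserved_within_5_percent(self):
        # geometry preservation of the rigid stage: jitter and elastic
        # distortion on, but no staining shrinkage or intensity drift
        # (those are corrected by later stages, not by rigid alignment)
        spec = PhantomSpec(
            grid_shape=(48, 64, 48), seed=4, damaged_fraction=0.0,
            shrink_factor=1.0, shrink_mod=0.0, drift_sigma=0.0, chatter=False,
        )
        blockface, stained, truth = section_phantom(spec)
        series = stained["nissl"]
        bf_t = align_blockface_stack(blockface, ref_index=len(blockface) // 2)
        bf_aligned = apply_transform_series(blockface, bf_t)
        coarse = coarse_align_to_blockface(series, bf_aligned)
        fine = fine_sequential_align(series, center_index=len(series) // 2)
        merged = coarse_to_fine_transforms(coarse, fine, sigma_sections=5.0)
        recon = reconstruct_rigid_volume(series, merged)
        clean = truth.clean["nissl"]
        lo = truth.section_offset
        hi = lo + len(blockface)
        clean_slab = clean.values[:, lo:hi, :]
        thr = 0.15 * clean.values.max()
        recon_vol = float((recon.values > thr).sum()) * np.prod(recon.spacing)
        clean_vol = float((clean_slab > thr).sum()) * np.prod(clean.spacing)
        assert abs(recon_vol - clean_vol) / clean_vol < 0.05

    def test_identity_transforms_give_plain_stack(self, small_phantom):
        _, blockface, _, _ = small_phantom
        center = image_center_mm(blockface.sections[0].shape, PS)
        identity = TransformSeries(
            [RigidTransform2D.identity(center) for _ in range(len(blockface))]
        )
        vol = reconstruct_rigid_volume(blockface, identity)
        np.testing.assert_allclose(
            vol.values, np.stack(blockface.sections, axis=1), atol=1e-12
        )
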