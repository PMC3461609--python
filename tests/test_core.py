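"""Grid geometry, rigid transforms, resampling and I/O round-trips."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ratpet import (
    DynamicImage,
    GeometryError,
    ImageVolume,
    RigidTransform,
    VoxelGrid,
    apply_transform,
    fit_rigid_landmarks,
    read_dynamic_nifti,
    read_nifti,
    write_dynamic_nifti,
    write_nifti,
)


class TestVoxelGrid:
    @pytest.mark.parametrize(
        "voxel_size,origin,index,expected",
        [
            ((1.218,) * 3, (0, 0, 0), (0, 0, 0), (0, 0, 0)),
            ((1.218,) * 3, (0, 0, 0), (1, 0, 0), (1.218, 0, 0)),
            ((0.1, 0.1, 0.13), (-5, -5, -5), (10, 10, 10), (-4.0, -4.0, -3.7)),
        ],
    )
    def test_voxel_to_world(self, voxel_size, origin, index, expected):
        grid = VoxelGrid((32, 32, 32), voxel_size, origin)
        np.testing.assert_allclose(grid.voxel_to_world(index), expected, atol=1e-12)

    def test_world_to_voxel_inverts_voxel_to_world(self):
        grid = VoxelGrid((8, 9, 10), (0.5, 0.7, 1.1), (-3.0, 2.0, 0.5))
        idx = np.array([1.25, -0.5, 7.75])
        np.testing.assert_allclose(grid.world_to_voxel(grid.voxel_to_world(idx)), idx)

    def test_invalid_grids_rejected(self):
        with pytest.raises(ValueError):
            VoxelGrid((0, 4, 4), (1, 1, 1))
        with pytest.raises(ValueError):
            VoxelGrid((4, 4, 4), (1, -1, 1))

    def test_centered_grid_is_symmetric(self):
        grid = VoxelGrid.centered((10, 12, 8), (1.0, 0.5, 2.0))
        for ax in range(3):
            coords = grid.axis_coordinates(ax)
            np.testing.assert_allclose(coords, -coords[::-1], atol=1e-12)


class TestRigidTransform:
    def test_compose_with_inverse_is_identity(self):
        t = RigidTransform((10.0, -25.0, 40.0), (3.0, -1.5, 7.0))
        np.testing.assert_allclose(t.compose(t.invert()).matrix(), np.eye(4), atol=1e-9)

    def test_invert_is_involution(self):
        t = RigidTransform((12.0, 7.0, -33.0), (0.4, 2.2, -5.0))
        np.testing.assert_allclose(t.invert().invert().matrix(), t.matrix(), atol=1e-9)

    def test_unit_scale_linear_part_is_proper_rotation(self):
        t = RigidTransform((17.0, -4.0, 122.0), (1.0, 2.0, 3.0))
        lin = t.linear
        np.testing.assert_allclose(lin.T @ lin, np.eye(3), atol=1e-12)
        assert np.linalg.det(lin) == pytest.approx(1.0, abs=1e-12)

    def test_apply_inverse_matches_invert_apply(self):
        t = RigidTransform((5.0, 10.0, -15.0), (1.0, -2.0, 0.5), (1.2, 1.2, 1.2))
        pts = np.random.default_rng(3).uniform(-5, 5, (20, 3))
        np.testing.assert_allclose(t.apply_inverse(pts), t.invert().apply(pts), atol=1e-10)

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(GeometryError):
            RigidTransform(scale=(1.0, 0.0, 1.0))

    def test_from_matrix_rejects_reflection(self):
        m = np.diag([-1.0, 1.0, 1.0, 1.0])
        with pytest.raises(GeometryError):
            RigidTransform.from_matrix(m)

    def test_json_roundtrip(self, tmp_path):
        t = RigidTransform((1.0, 2.0, 3.0), (-4.0, 5.0, -6.0))
        path = tmp_path / "t.json"
        t.to_json(path)
        back = RigidTransform.from_json(path)
        np.testing.assert_allclose(back.matrix(), t.matrix(), atol=1e-12)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        rot=st.tuples(*[st.floats(-180, 180) for _ in range(3)]),
        tra=st.tuples(*[st.floats(-20, 20) for _ in range(3)]),
    )
    def test_matrix_decomposition_roundtrip(self, rot, tra):
        t = RigidTransform(rot, tra)
        back = RigidTransform.from_matrix(t.matrix())
        np.testing.assert_allclose(back.matrix(), t.matrix(), atol=1e-9)


class TestFitRigidLandmarks:
    def test_exact_recovery_noiseless(self):
        truth = RigidTransform((0.0, 0.0, 10.0), (2.0, 1.0, 0.0))
        src = np.array([[0, 0, 0], [5, 0, 0], [0, 5, 0], [0, 0, 5]], dtype=float)
        fitted = fit_rigid_landmarks(src, truth.apply(src))
        np.testing.assert_allclose(fitted.rotation_deg, truth.rotation_deg, atol=1e-6)
        np.testing.assert_allclose(fitted.translation_mm, truth.translation_mm, atol=1e-6)

    def test_too_few_points_rejected(self):
        pts = np.array([[0, 0, 0], [1, 0, 0]], dtype=float)
        with pytest.raises(GeometryError):
            fit_rigid_landmarks(pts, pts)

    def test_collinear_points_rejected(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], dtype=float)
        with pytest.raises(GeometryError):
            fit_rigid_landmarks(pts, pts + 1.0)

    def test_noisy_rms_residual_matches_chi_square_expectation(self):
        # LSQ over 6 DOF on 3N coordinates: E[SS] = sigma^2 (3N - 6), so the
        # per-point RMS converges to sigma * sqrt((3N - 6) / N).
        rng = np.random.default_rng(42)
        sigma, n = 0.1, 100
        truth = RigidTransform((5.0, -3.0, 8.0), (1.0, 2.0, -1.0))
        rms = []
        for _ in range(100):
            src = rng.uniform(-10, 10, (n, 3))
            dst = truth.apply(src) + rng.normal(0, sigma, (n, 3))
            fitted = fit_rigid_landmarks(src, dst)
            resid = fitted.apply(src) - dst
            rms.append(np.sqrt((resid**2).sum() / n))
        expected = sigma * np.sqrt((3 * n - 6) / n)
        assert np.mean(rms) == pytest.approx(expected, rel=0.2)


class TestApplyTransform:
    @pytest.fixture()
    def bar_image(self):
        grid = VoxelGrid.centered((40, 40, 40), (1.218,) * 3)
        vals = np.zeros(grid.shape)
        vals[17:23, 12:28, 17:23] = 7.0  # bar along y, >= 5 voxels off the border
        return ImageVolume(grid, vals)

    def test_identity_same_grid_is_lossless(self, bar_image):
        out = apply_transform(bar_image, RigidTransform.identity(), bar_image.grid)
        assert np.array_equal(out.values, bar_image.values)

    def test_one_voxel_translation_nearest_is_integer_shift(self):
        grid = VoxelGrid((12, 10, 9), (1.218,) * 3)
        rng = np.random.default_rng(7)
        img = ImageVolume(grid, rng.uniform(0, 5, grid.shape))
        out = apply_transform(
            img, RigidTransform(translation_mm=(1.218, 0, 0)), grid, interpolation="nearest"
        )
        np.testing.assert_allclose(out.values[1:], img.values[:-1], atol=1e-12)
        np.testing.assert_allclose(out.values[0], 0.0)

    def test_rotation_90deg_swaps_bar_axis_and_conserves_activity(self, bar_image):
        out = apply_transform(bar_image, RigidTransform((0, 0, 90)), bar_image.grid)
        assert out.values.sum() == pytest.approx(bar_image.values.sum(), rel=0.01)
        x_extent = np.flatnonzero(out.values.sum(axis=(1, 2)))
        y_extent = np.flatnonzero(out.values.sum(axis=(0, 2)))
        assert len(x_extent) > len(y_extent)  # bar now lies along x

    def test_trilinear_stays_within_input_range(self, bar_image):
        out = apply_transform(
            bar_image, RigidTransform((3.0, 5.0, -7.0), (0.3, -0.2, 0.9)), bar_image.grid
        )
        assert out.values.min() >= min(0.0, bar_image.values.min()) - 1e-9
        assert out.values.max() <= max(0.0, bar_image.values.max()) + 1e-9

    def test_degenerate_scale_rejected(self):
        # scale validation happens at transform construction
        with pytest.raises(GeometryError):
            RigidTransform((0, 0, 0), (0, 0, 0), (1.0, 1.0, -1.0))


class TestNiftiIO:
    def test_volume_roundtrip(self, tmp_path):
        grid = VoxelGrid((6, 7, 8), (0.5, 0.6, 0.7), (-1.0, 2.0, 3.0))
        img = ImageVolume(grid, np.random.default_rng(0).uniform(0, 1, grid.shape))
        path = tmp_path / "img.nii.gz"
        write_nifti(img, path)
        back = read_nifti(path)
        # NIfTI headers store geometry in float32
        assert back.grid.shape == grid.shape
        np.testing.assert_allclose(back.grid.voxel_size, grid.voxel_size, rtol=1e-6)
        np.testing.assert_allclose(back.grid.origin, grid.origin, atol=1e-5)
        np.testing.assert_allclose(back.values, img.values.astype(np.float32), atol=1e-7)

    def test_dynamic_roundtrip_preserves_schedule(self, tmp_path):
        grid = VoxelGrid((5, 5, 5), (1.0, 1.0, 1.0))
        rng = np.random.default_rng(1)
        frames = [ImageVolume(grid, rng.uniform(0, 2, grid.shape)) for _ in range(4)]
        schedule = [(0.0, 10.0), (10.0, 10.0), (20.0, 30.0), (50.0, 60.0)]
        dyn = DynamicImage(frames, schedule)
        path = tmp_path / "dyn.nii.gz"
        write_dynamic_nifti(dyn, path)
        back = read_dynamic_nifti(path)
        assert back.schedule == schedule
        for fa, fb in zip(back.frames, dyn.frames):
            np.testing.assert_allclose(fa.values, fb.values.astype(np.float32), atol=1e-7)


class TestDynamicImageInvariants:
    def test_overlapping_frames_rejected(self):
        grid = VoxelGrid((3, 3, 3), (1, 1, 1))
        frames = [ImageVolume(grid, np.zeros(grid.shape)) for _ in range(2)]
        with pytest.raises(ValueError):
            DynamicImage(frames, [(0.0, 20.0), (10.0, 10.0)])

    def test_schedule_length_mismatch_rejected(self):
        grid = VoxelGrid((3, 3, 3), (1, 1, 1))
        frames = [ImageVolume(grid, np.zeros(grid.shape))]
        with pytest.raises(ValueError):
            DynamicImage(frames, [(0.0, 10.0), (10.0, 10.0)])
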