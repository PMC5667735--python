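import math

import numpy as np
import pytest
from scipy.interpolate import RegularGridInterpolator

from saliency3d import (
    CubeGrid,
    LabVolume,
    MultiScaleConfig,
    SaliencyMap,
    axis_plane_indices,
    brute_force_saliency,
    color_saliency,
    cube_decompose,
    fuse_scales,
    median_smooth,
    nominal_comparison_counts,
    spatial_weighted_saliency,
    upscale_map,
)
from saliency3d.errors import ValidationError

from conftest import random_cube_grids


def _lab_volume(data):
    return LabVolume(np.asarray(data, dtype=float))


def _odd_cube_grid():
    """2x2x2 grid with one cube at (100, 0, 0) and the rest at the origin."""
    means = np.zeros((2, 2, 2, 3))
    means[0, 0, 0] = (100.0, 0.0, 0.0)
    return CubeGrid(k=1, means=means)


class TestCubeDecompose:
    def test_constant_volume_single_cube(self):
        data = np.zeros((4, 4, 4, 3))
        data[..., 0] = 50.0
        grid = cube_decompose(_lab_volume(data), 4)
        assert grid.dims == (1, 1, 1)
        assert np.allclose(grid.means[0, 0, 0], (50.0, 0.0, 0.0))

    def test_cube_counts(self):
        data = np.zeros((24, 24, 24, 3))
        assert cube_decompose(_lab_volume(data), 4).dims == (6, 6, 6)
        assert cube_decompose(_lab_volume(data), 8).dims == (3, 3, 3)

    def test_mean_conservation(self):
        rng = np.random.default_rng(21)
        data = rng.uniform(-50, 100, (16, 8, 24, 3))
        grid = cube_decompose(_lab_volume(data), 4)
        assert np.allclose(grid.means.mean(axis=(0, 1, 2)), data.mean(axis=(0, 1, 2)), atol=1e-9)

    def test_block_mean_matches_direct_slice(self):
        rng = np.random.default_rng(22)
        data = rng.uniform(0, 100, (8, 8, 8, 3))
        grid = cube_decompose(_lab_volume(data), 4)
        assert np.allclose(grid.means[1, 0, 1], data[4:8, 0:4, 4:8].mean(axis=(0, 1, 2)))

    def test_non_divisible_raises(self):
        with pytest.raises(ValidationError, match="conform"):
            cube_decompose(_lab_volume(np.zeros((6, 8, 8, 3))), 4)


class TestAxisPlaneIndices:
    def _brute(self, idx, dims):
        i, j, l = idx
        out = set()
        for x in range(dims[0]):
            for y in range(dims[1]):
                for z in range(dims[2]):
                    same = (x, y, z) == (i, j, l)
                    if not same and (x == i or y == j or z == l):
                        out.add((x, y, z))
        return out

    @pytest.mark.parametrize("dims", [(2, 2, 2), (3, 4, 5), (1, 1, 1), (1, 3, 2)])
    def test_matches_exhaustive_enumeration(self, dims):
        for idx in np.ndindex(*dims):
            assert axis_plane_indices(idx, dims) == self._brute(idx, dims)

    def test_single_cube_has_no_neighbours(self):
        assert axis_plane_indices((0, 0, 0), (1, 1, 1)) == set()

    def test_size_by_inclusion_exclusion(self):
        # |union| = 3*plane - 3*line + 1 (triple) - 1 (self) for a cubic grid
        assert len(axis_plane_indices((5, 7, 9), (60, 60, 60))) == 3 * 3600 - 3 * 60 + 1 - 1

    def test_out_of_range_raises(self):
        with pytest.raises(ValidationError):
            axis_plane_indices((2, 0, 0), (2, 2, 2))


class TestColorSaliency:
    def test_uniform_grid_is_zero(self):
        means = np.full((3, 4, 5, 3), 7.0)
        assert np.all(color_saliency(CubeGrid(k=1, means=means)) == 0)

    def test_odd_cube_hand_value(self):
        Sc = color_saliency(_odd_cube_grid())
        assert Sc[0, 0, 0] == pytest.approx(600.0, abs=1e-9)
        # every other cube sees the odd cube iff it shares a coordinate
        assert Sc[1, 1, 1] == pytest.approx(0.0, abs=1e-9)

    def test_axis_permutation_equivariance(self):
        rng = np.random.default_rng(23)
        means = rng.uniform(0, 100, (4, 4, 4, 3))
        base = color_saliency(CubeGrid(k=1, means=means))
        for perm in [(1, 0, 2), (2, 1, 0), (1, 2, 0)]:
            permuted = color_saliency(CubeGrid(k=1, means=np.transpose(means, (*perm, 3))))
            assert np.allclose(permuted, np.transpose(base, perm), atol=1e-9)


class TestSpatialWeightedSaliency:
    def test_uniform_grid_zero_both_modes(self):
        means = np.full((3, 3, 3, 3), 2.0)
        grid = CubeGrid(k=1, means=means)
        assert np.all(spatial_weighted_saliency(grid, "per_pair") == 0)
        assert np.all(spatial_weighted_saliency(grid, "factored") == 0)

    def test_odd_cube_hand_value_per_pair(self):
        S = spatial_weighted_saliency(_odd_cube_grid(), "per_pair")
        expected = 3 * (100 / 2.0) + 3 * (100 / (1 + math.sqrt(2)))
        assert S[0, 0, 0] == pytest.approx(expected, abs=1e-9)

    def test_bounded_by_half_color_saliency(self):
        for grid in random_cube_grids(10, seed=24):
            Sc = color_saliency(grid)
            S = spatial_weighted_saliency(grid, "per_pair")
            assert np.all(S <= Sc / 2 + 1e-9)
            assert np.all(S >= 0)

    def test_unknown_mode_raises(self):
        with pytest.raises(ValidationError, match="mode"):
            spatial_weighted_saliency(_odd_cube_grid(), "nearest")


class TestBruteForceOracle:
    def test_production_matches_oracle(self):
        for grid in random_cube_grids(10, seed=25):
            for mode in ("per_pair", "factored"):
                bSc, bS = brute_force_saliency(grid, mode)
                assert np.allclose(color_saliency(grid), bSc, rtol=1e-9, atol=1e-9)
                assert np.allclose(
                    spatial_weighted_saliency(grid, mode), bS, rtol=1e-9, atol=1e-9
                )

    def test_odd_cube_cross_check(self):
        Sc, _ = brute_force_saliency(_odd_cube_grid())
        assert Sc[0, 0, 0] == pytest.approx(600.0)

    def test_guard_on_large_grids(self):
        with pytest.raises(ValidationError, match="guard"):
            brute_force_saliency(CubeGrid(k=1, means=np.zeros((9, 2, 2, 3))))


class TestUpscaleMap:
    def test_constant_grid(self):
        out = upscale_map(np.full((3, 3, 3), 4.2), 4, (12, 12, 12))
        assert out.shape == (12, 12, 12)
        assert np.allclose(out, 4.2)

    def test_bounded_by_grid_extremes(self):
        rng = np.random.default_rng(26)
        grid = rng.uniform(-5, 17, (4, 3, 5))
        out = upscale_map(grid, 4, (16, 12, 20))
        assert out.min() >= grid.min() - 1e-12
        assert out.max() <= grid.max() + 1e-12

    def test_matches_center_anchored_interpolation_oracle(self):
        """Full-map comparison against an independently constructed
        centre-anchored trilinear interpolant with edge clamping."""
        rng = np.random.default_rng(27)
        k = 4
        grid = rng.uniform(0, 100, (5, 4, 3))
        target = tuple(d * k for d in grid.shape)
        out = upscale_map(grid, k, target)

        centers = [np.arange(d) * k + (k - 1) / 2.0 for d in grid.shape]
        rgi = RegularGridInterpolator(centers, grid)
        pts = np.stack(
            np.meshgrid(*[np.arange(t, dtype=float) for t in target], indexing="ij"), axis=-1
        )
        for axis in range(3):
            pts[..., axis] = np.clip(pts[..., axis], centers[axis][0], centers[axis][-1])
        expected = rgi(pts.reshape(-1, 3)).reshape(target)
        assert np.allclose(out, expected, atol=1e-9)

    def test_linear_ramp_reproduced_in_interior(self):
        # a ramp in cube index space upscales to a ramp in voxel space
        k = 4
        grid = np.arange(6, dtype=float)[:, None, None] * np.ones((6, 2, 2))
        out = upscale_map(grid, k, (24, 8, 8))
        p = np.arange(2, 22)  # interior voxels between the outermost centres
        assert np.allclose(out[p, 0, 0], (p - 1.5) / k, atol=1e-9)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValidationError):
            upscale_map(np.zeros((2, 2, 2)), 4, (8, 8, 9))


class TestFuseScales:
    def test_identical_maps_pass_through(self):
        rng = np.random.default_rng(28)
        m = rng.uniform(0, 1, (8, 8, 8))
        cfg = MultiScaleConfig(scales=(4, 8), weights=(0.5, 0.5))
        fused = fuse_scales({4: m, 8: m}, cfg)
        expected = 255.0 * (m - m.min()) / (m.max() - m.min())
        assert np.allclose(fused.data, expected, atol=1e-9)

    def test_all_zero_maps_fuse_to_zero(self):
        cfg = MultiScaleConfig(scales=(4, 8), weights=(0.5, 0.5))
        fused = fuse_scales({4: np.zeros((4, 4, 4)), 8: np.zeros((4, 4, 4))}, cfg)
        assert np.all(fused.data == 0)

    def test_default_weights_are_equal_thirds(self):
        cfg = MultiScaleConfig()
        assert cfg.scales == (4, 8, 16)
        assert np.allclose(cfg.weights, (1 / 3, 1 / 3, 1 / 3))

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValidationError, match="sum"):
            MultiScaleConfig(scales=(4, 8), weights=(0.5, 0.6))

    def test_scale_mismatch_raises(self):
        cfg = MultiScaleConfig(scales=(4, 8), weights=(0.5, 0.5))
        with pytest.raises(ValidationError):
            fuse_scales({4: np.zeros((4, 4, 4))}, cfg)


class TestMedianSmooth:
    def test_uniform_unchanged(self):
        m = SaliencyMap(np.full((6, 6, 6), 9.0))
        assert np.array_equal(median_smooth(m, 3).data, m.data)

    def test_impulse_removed(self):
        data = np.full((7, 7, 7), 10.0)
        data[3, 3, 3] = 255.0
        out = median_smooth(SaliencyMap(data), 3)
        assert out.data[3, 3, 3] == 10.0

    def test_kernel_one_is_identity(self):
        rng = np.random.default_rng(29)
        m = SaliencyMap(rng.uniform(0, 255, (5, 5, 5)))
        assert np.array_equal(median_smooth(m, 1).data, m.data)

    def test_even_kernel_raises(self):
        with pytest.raises(ValidationError):
            median_smooth(SaliencyMap(np.zeros((4, 4, 4))), 2)


class TestNominalComparisonCounts:
    @pytest.mark.parametrize(
        "M,N,k,expected",
        [
            (240, 240, 4, (216_000, 46_655_784_000, 2_332_800_000)),
            (240, 240, 8, (27_000, 728_973_000, 72_900_000)),
        ],
    )
    def test_published_operation_counts(self, M, N, k, expected):
        assert nominal_comparison_counts(M, N, k) == expected

    def test_non_square_through_plane(self):
        n_cubes, all_pairs, axis_plane = nominal_comparison_counts(16, 8, 4)
        assert n_cubes == 4 * 4 * 2
        assert all_pairs == 32 * 31
        assert axis_plane == 32 * (4 * 4 + 2 * 4 * 2)

    def test_non_divisible_raises(self):
        with pytest.raises(ValidationError):
            nominal_comparison_counts(240, 155, 16)
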