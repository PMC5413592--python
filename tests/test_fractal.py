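"""Fractal dimensionality estimators against analytic and enumeration oracles."""

import math

import numpy as np
import pytest

from morphrel import fractal, phantoms
from morphrel.io_formats import BinaryMask, LabelVolume, RegionLookup

MENGER_FD = math.log(20) / math.log(3)


def _boxcount_oracle(data: np.ndarray, scale: int) -> int:
    """Independent brute-force box occupancy count (explicit triple loop)."""
    from scipy import ndimage

    sl = ndimage.find_objects(data.astype(np.int8))[0]
    data = data[sl]
    count = 0
    for i in range(0, data.shape[0], scale):
        for j in range(0, data.shape[1], scale):
            for k in range(0, data.shape[2], scale):
                if data[i : i + scale, j : j + scale, k : k + scale].any():
                    count += 1
    return count


class TestExtractSurface:
    def test_cube_shell(self):
        shell = fractal.extract_surface(phantoms.filled_cube(4))
        assert shell.count == 56

    def test_cube3_loses_only_center(self):
        shell = fractal.extract_surface(phantoms.filled_cube(3))
        assert shell.count == 26
        assert not shell.data[1, 1, 1]

    def test_single_voxel_is_its_own_surface(self):
        data = np.zeros((5, 5, 5), bool)
        data[2, 2, 2] = True
        shell = fractal.extract_surface(BinaryMask(data))
        np.testing.assert_array_equal(shell.data, data)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            fractal.extract_surface(BinaryMask(np.zeros((3, 3, 3), bool)))


class TestBoxcountSeries:
    def test_menger_self_similarity(self):
        series = fractal.boxcount_series(phantoms.menger_sponge(2), [1, 3, 9])
        np.testing.assert_array_equal(series.counts, [400, 20, 1])

    def test_power_of_two_cube_is_exact(self):
        series = fractal.boxcount_series(phantoms.filled_cube(16), [1, 2, 4, 8, 16])
        np.testing.assert_array_equal(series.counts, [4096, 512, 64, 8, 1])

    def test_single_voxel_counts_are_one(self):
        data = np.zeros((6, 6, 6), bool)
        data[3, 3, 3] = True
        series = fractal.boxcount_series(BinaryMask(data), [1, 2, 4])
        np.testing.assert_array_equal(series.counts, [1, 1, 1])

    def test_matches_brute_force_on_random_blobs(self):
        for seed in range(5):
            mask = phantoms.random_blob(grid=24, seed=seed)
            for s in (1, 2, 3, 4):
                series = fractal.boxcount_series(mask, [s, s + 4, s + 9])
                assert series.counts[0] == _boxcount_oracle(mask.data, s)

    def test_scale_larger_than_grid_rejected(self):
        with pytest.raises(ValueError):
            fractal.boxcount_series(phantoms.filled_cube(8), [1, 2, 16])


class TestDilationSeries:
    def test_scale_one_is_voxel_count(self):
        mask = phantoms.random_blob(seed=3)
        series = fractal.dilation_series(mask, [1, 2, 4])
        assert series.counts[0] == mask.count

    def test_cube_fd_near_three(self):
        res = fractal.fit_fd(fractal.dilation_series(phantoms.filled_cube(16), [1, 2, 4, 8]))
        assert abs(res.fd - 3.0) < 0.1

    def test_translation_invariance(self):
        base = np.zeros((48, 48, 48), bool)
        base[16:28, 18:30, 14:26] = phantoms.random_blob(grid=12, seed=5, n_seeds=4, dilate_iters=2).data
        scales = [1, 2, 4, 8]
        ref = fractal.dilation_series(BinaryMask(base), scales).counts
        for shift in [(1, 1, 1), (3, 5, 2), (-4, 0, 6)]:
            moved = np.roll(base, shift, axis=(0, 1, 2))
            got = fractal.dilation_series(BinaryMask(moved), scales).counts
            np.testing.assert_array_equal(got, ref)

    def test_counts_non_increasing_on_random_blobs(self):
        # the ScaleSeries constructor enforces monotonicity; this exercises it
        for seed in range(100):
            mask = phantoms.random_blob(grid=48, seed=seed)
            fractal.dilation_series(mask, [1, 2, 4, 8])
            fractal.boxcount_series(mask, [1, 2, 4, 8])


class TestFitFD:
    def test_exact_geometric_series(self):
        series = fractal.ScaleSeries(scales=[1, 3, 9], counts=[400, 20, 1])
        res = fractal.fit_fd(series)
        assert res.fd == pytest.approx(MENGER_FD, abs=1e-12)
        assert res.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_cube_series_gives_three(self):
        series = fractal.ScaleSeries(scales=[1, 2, 4, 8, 16], counts=[4096, 512, 64, 8, 1])
        assert fractal.fit_fd(series).fd == pytest.approx(3.0, abs=1e-12)

    def test_flat_series_gives_zero(self):
        series = fractal.ScaleSeries(scales=[1, 2, 4], counts=[7, 7, 7])
        assert fractal.fit_fd(series).fd == pytest.approx(0.0, abs=1e-12)

    def test_zero_count_rejected_by_series(self):
        with pytest.raises(ValueError):
            fractal.ScaleSeries(scales=[1, 2, 4], counts=[10, 1, 0])


class TestFD:
    def test_menger3_boxcount(self):
        res = fractal.fd(phantoms.menger_sponge(3), "boxcount", "filled", [1, 3, 9, 27])
        assert res.fd == pytest.approx(MENGER_FD, abs=1e-9)

    def test_cube_surface_matches_shell_enumeration(self):
        # oracle: exact box counts of the one-voxel shell
        shell = fractal.extract_surface(phantoms.filled_cube(64))
        oracle_counts = [_boxcount_oracle(shell.data, s) for s in (1, 2, 4, 8)]
        res = fractal.fd(phantoms.filled_cube(64), "boxcount", "surface", [1, 2, 4, 8])
        series = fractal.boxcount_series(shell, [1, 2, 4, 8])
        np.testing.assert_array_equal(series.counts, oracle_counts)
        assert abs(res.fd - 2.0) < 0.15

    def test_sphere_dilation_agrees_with_boxcount(self):
        mask = phantoms.sphere_mask(radius=20, grid=64)
        fd_dil = fractal.fd(mask, "dilation", "filled", [1, 2, 4, 8, 16]).fd
        fd_box = fractal.fd(mask, "boxcount", "filled", [1, 2, 4, 8, 16]).fd
        assert abs(fd_dil - fd_box) < 0.2

    @pytest.mark.parametrize("maker,expected,tol", [
        (lambda: phantoms.slab_mask(64), 2.0, 0.15),
        (lambda: phantoms.line_mask(64), 1.0, 0.15),
    ])
    @pytest.mark.parametrize("algorithm", ["boxcount", "dilation"])
    def test_euclidean_limits(self, maker, expected, tol, algorithm):
        res = fractal.fd(maker(), algorithm, "filled", [1, 2, 4, 8])
        assert abs(res.fd - expected) < tol

    def test_result_is_tagged(self):
        res = fractal.fd(phantoms.filled_cube(16), "boxcount", "surface", [1, 2, 4, 8])
        assert res.algorithm == "boxcount"
        assert res.variant == "surface"
        assert res.scales_used == (1, 2, 4, 8)


class TestRegionalFD:
    def _two_cube_volume(self):
        # second cube offset by 24 voxels: keeps both aligned to the 8-voxel grid
        data = np.zeros((44, 44, 44), np.int32)
        data[2:18, 2:18, 2:18] = 1
        data[26:42, 26:42, 26:42] = 2
        return LabelVolume(data=data, affine=np.eye(4), voxel_size_mm=np.ones(3))

    def test_two_cubes_both_near_three(self):
        vol = self._two_cube_volume()
        lookup = RegionLookup(entries=[(1, "cube_a"), (2, "cube_b")])
        table = fractal.regional_fd(vol, lookup, "boxcount", "filled", [1, 2, 4, 8])
        assert len(table) == 2
        assert np.all(np.abs(table["fd"].values - 3.0) < 1e-9)

    def test_single_label_consistent_with_fd(self):
        vol = self._two_cube_volume()
        lookup = RegionLookup(entries=[(1, "cube_a")])
        table = fractal.regional_fd(vol, lookup, "dilation", "filled", [1, 2, 4, 8])
        # oracle: the same cropped+padded mask through the plain estimator
        from scipy import ndimage

        sl = ndimage.find_objects((vol.data == 1).astype(np.int8))[0]
        cropped = np.pad(vol.data[sl] == 1, 1)
        direct = fractal.fd(BinaryMask(cropped), "dilation", "filled", [1, 2, 4, 8])
        assert table["fd"].iloc[0] == pytest.approx(direct.fd, abs=1e-12)

    def test_absent_label_skipped_with_warning(self):
        vol = self._two_cube_volume()
        lookup = RegionLookup(entries=[(1, "cube_a"), (9, "ghost")])
        with pytest.warns(UserWarning, match="ghost"):
            table = fractal.regional_fd(vol, lookup, "boxcount", "filled", [1, 2, 4, 8])
        assert table["code"].tolist() == [1]

    def test_small_region_flagged_unreliable(self):
        data = np.zeros((20, 20, 20), np.int32)
        data[2:18, 2:18, 2:18] = 1
        data[0, 0, :3] = 2  # 3 voxels
        vol = LabelVolume(data=data, affine=np.eye(4), voxel_size_mm=np.ones(3))
        lookup = RegionLookup(entries=[(1, "big"), (2, "tiny")])
        table = fractal.regional_fd(vol, lookup, "boxcount", "filled", [1, 2, 3])
        flags = dict(zip(table["name"], table["unreliable"]))
        assert not flags["big"] and flags["tiny"]

    def test_region_fd_not_above_whole(self):
        vol = self._two_cube_volume()
        lookup = RegionLookup(entries=[(1, "cube_a"), (2, "cube_b")])
        table = fractal.regional_fd(vol, lookup, "boxcount", "filled", [1, 2, 4, 8])
        whole = fractal.fd(
            BinaryMask(vol.data > 0), "boxcount", "filled", [1, 2, 4, 8]
        )
        assert np.all(table["fd"].values <= whole.fd + 1e-9)
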