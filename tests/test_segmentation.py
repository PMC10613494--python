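from collections import deque

import numpy as np
import pytest

import atriflow as af


def vol(values, spacing=1.0):
    grid = af.ImageGrid.from_spacing(values.shape, spacing)
    return af.ScalarVolume(grid, values)


def flood_fill_bfs(values, seed_idx, lower, upper):
    """Independent breadth-first flood fill through face neighbours."""
    shape = values.shape
    visited = np.zeros(shape, dtype=bool)
    queue = deque([tuple(seed_idx)])
    while queue:
        p = queue.popleft()
        if visited[p]:
            continue
        if not (lower <= values[p] <= upper):
            continue
        visited[p] = True
        for axis in range(3):
            for step in (-1, 1):
                q = list(p)
                q[axis] += step
                if 0 <= q[axis] < shape[axis]:
                    queue.append(tuple(q))
    return visited


class TestBiasCorrect:
    def test_flat_field_unchanged(self):
        v = vol(np.full((12, 12, 12), 7.0))
        out = af.bias_correct(v)
        assert np.abs(out.values - 7.0).max() < 7.0 * 1e-6

    def test_linear_ramp_flattened(self):
        shape = (120, 10, 10)  # 240 mm FOV at 2 mm spacing, thorax-like
        ramp = np.linspace(0.5, 1.5, shape[0])[:, None, None]
        v = vol(np.broadcast_to(100.0 * ramp, shape).copy(), spacing=2.0)
        out = af.bias_correct(v, scale_mm=25.0)
        cv_before = v.values.std() / v.values.mean()
        cv_after = out.values.std() / out.values.mean()
        assert cv_before / cv_after >= 5.0

    def test_zero_volume_warns_unchanged(self):
        v = vol(np.zeros((5, 5, 5)))
        with pytest.warns(UserWarning):
            out = af.bias_correct(v)
        assert np.all(out.values == 0.0)

    def test_mean_preserved(self):
        rng = np.random.default_rng(0)
        v = vol(rng.uniform(10, 20, (16, 16, 16)))
        out = af.bias_correct(v)
        assert out.values.mean() == pytest.approx(v.values.mean(), rel=1e-9)


class TestRegionGrow:
    def test_uniform_volume_fills_everything(self):
        v = vol(np.full((8, 8, 8), 5.0))
        seeds = af.SeedSpec(((3.0, 3.0, 3.0),), 4.0, 6.0, "LA")
        assert af.region_grow(v, seeds).count == 8**3

    def test_matches_bfs_oracle_on_two_blobs(self):
        values = np.zeros((20, 20, 20))
        values[2:8, 2:8, 2:8] = 100.0
        values[12:18, 12:18, 12:18] = 100.0
        v = vol(values)
        seeds = af.SeedSpec(((4.0, 4.0, 4.0),), 50.0, 150.0, "LA")
        grown = af.region_grow(v, seeds)
        oracle = flood_fill_bfs(values, (4, 4, 4), 50.0, 150.0)
        assert np.array_equal(grown.values, oracle)
        assert grown.count == 6**3  # exactly blob 1

    def test_matches_bfs_oracle_on_random_fields(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            values = rng.uniform(0, 1, (12, 12, 12))
            seed_idx = tuple(rng.integers(0, 12, 3))
            lo, hi = 0.0, 0.6
            values[seed_idx] = 0.3  # keep the seed inside the window
            v = vol(values)
            seeds = af.SeedSpec((tuple(map(float, seed_idx)),), lo, hi, "OTHER")
            grown = af.region_grow(v, seeds)
            oracle = flood_fill_bfs(values, seed_idx, lo, hi)
            assert np.array_equal(grown.values, oracle)

    def test_seed_outside_window_is_an_error(self):
        values = np.zeros((10, 10, 10))
        values[2:5, 2:5, 2:5] = 100.0
        v = vol(values)
        seeds = af.SeedSpec(((7.0, 7.0, 7.0),), 50.0, 150.0, "LA")
        with pytest.raises(ValueError, match="seed intensity"):
            af.region_grow(v, seeds)

    def test_seed_off_grid_is_an_error(self):
        v = vol(np.ones((5, 5, 5)))
        with pytest.raises(ValueError, match="outside the image grid"):
            af.region_grow(v, af.SeedSpec(((50.0, 0.0, 0.0),), 0.0, 2.0))


def cube_mask(shape=(30, 30, 30), lo=5, hi=25, spacing=1.0):
    values = np.zeros(shape, dtype=bool)
    values[lo:hi, lo:hi, lo:hi] = True
    grid = af.ImageGrid.from_spacing(shape, spacing)
    return af.BinaryMask(grid, values, "LA")


class TestRefineSegment:
    def test_solid_cube_nearly_unchanged(self):
        mask = cube_mask()
        out = af.refine_segment(mask, kernel_mm=3.0)
        assert abs(out.count - mask.count) / mask.count < 0.05

    def test_interior_hole_filled(self):
        mask = cube_mask()
        values = mask.values.copy()
        values[15, 15, 15] = False
        out = af.refine_segment(mask.with_values(values), kernel_mm=3.0)
        assert out.values[15, 15, 15]

    def test_isolated_voxel_removed(self):
        values = np.zeros((15, 15, 15), dtype=bool)
        values[7, 7, 7] = True
        grid = af.ImageGrid.from_spacing(values.shape, 1.0)
        out = af.refine_segment(af.BinaryMask(grid, values, "OTHER"), kernel_mm=3.0)
        assert out.count == 0

    def test_idempotent_on_convex_input(self):
        mask = cube_mask()
        once = af.refine_segment(mask)
        twice = af.refine_segment(once)
        changed = np.logical_xor(once.values, twice.values).sum()
        assert changed < 0.01 * once.count


class TestCutAtPlane:
    def test_plane_outside_bbox_is_noop(self):
        mask = cube_mask()
        kept, removed = af.cut_at_plane(mask, (100.0, 0.0, 0.0), (1.0, 0.0, 0.0),
                                        (15.0, 15.0, 15.0))
        assert np.array_equal(kept.values, mask.values)
        assert removed.count == 0

    def test_midplane_splits_box_exactly(self):
        values = np.zeros((12, 12, 22), dtype=bool)
        values[1:11, 1:11, 1:21] = True  # 10 x 10 x 20 box
        grid = af.ImageGrid.from_spacing(values.shape, 1.0)
        mask = af.BinaryMask(grid, values, "LA")
        kept, removed = af.cut_at_plane(mask, (0.0, 0.0, 10.5), (0.0, 0.0, 1.0),
                                        (5.0, 5.0, 15.0))
        assert kept.count == 10 * 10 * 10
        assert removed.count == 10 * 10 * 10

    def test_dumbbell_cut_keeps_single_component(self):
        from scipy import ndimage

        values = np.zeros((30, 10, 10), dtype=bool)
        values[2:12, 2:8, 2:8] = True
        values[18:28, 2:8, 2:8] = True
        values[12:18, 4:6, 4:6] = True  # thin neck
        grid = af.ImageGrid.from_spacing(values.shape, 1.0)
        mask = af.BinaryMask(grid, values, "LA")
        kept, removed = af.cut_at_plane(mask, (15.0, 0.0, 0.0), (1.0, 0.0, 0.0),
                                        (5.0, 5.0, 5.0))
        _, n_components = ndimage.label(kept.values)
        assert n_components == 1
        assert kept.count > 0 and removed.count > 0

    def test_partition_property(self):
        rng = np.random.default_rng(3)
        values = ndimage_blob(rng)
        grid = af.ImageGrid.from_spacing(values.shape, 1.5)
        mask = af.BinaryMask(grid, values, "LA")
        keep_idx = np.argwhere(values)[0]
        keep_point = grid.world_from_index(keep_idx)
        kept, removed = af.cut_at_plane(mask, (10.0, 8.0, 9.0),
                                        tuple(rng.normal(size=3)), tuple(keep_point))
        assert np.array_equal(kept.values | removed.values, mask.values)
        assert not np.any(kept.values & removed.values)

    def test_keep_point_outside_mask_is_an_error(self):
        mask = cube_mask()
        with pytest.raises(ValueError, match="not inside the mask"):
            af.cut_at_plane(mask, (0.0, 0.0, 0.0), (1.0, 0.0, 0.0), (0.0, 0.0, 0.0))


def ndimage_blob(rng):
    from scipy import ndimage

    field = ndimage.gaussian_filter(rng.normal(size=(16, 16, 16)), 2.0)
    return field > np.percentile(field, 70)
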