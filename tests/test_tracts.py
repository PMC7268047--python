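"""Tract extraction: tracker semantics, thresholds, slice ROI, template."""

import numpy as np
import pytest

from tractrr.errors import EmptyTractError, MaskError
from tractrr.tensor import ScalarMaps
from tractrr.tracts import (
    ROIMask,
    TrackerParams,
    TractDensityMap,
    apply_fa_threshold,
    apply_template,
    combine_component_tracts,
    extract_metrics,
    normalize_and_threshold_tract,
    peduncle_roi,
    track_probabilistic,
)


def _single_seed(masks, grid):
    seeds = np.zeros(grid, bool)
    seeds[tuple(np.argwhere(masks["seeds"])[0])] = True
    return seeds


class TestTracker:
    def test_deterministic_corridor(self, small_phantom):
        """Zero dispersion, single seed: waytotal = n_samples and the visited
        corridor is traversed by every streamline."""
        m = small_phantom["masks"]
        grid = small_phantom["spec"].grid_shape
        seeds = _single_seed(m, grid)
        params = TrackerParams(n_samples=100, angular_sd_deg=0.0, seed=5)
        dens = track_probabilistic(
            small_phantom["maps"], small_phantom["v1"], seeds,
            waypoints=[m["plic"], m["peduncle"]],
            exclusions=[m["midline_exclusion"]],
            params=params,
        )
        assert dens.waytotal == 100
        visited = dens.counts > 0
        assert visited.any()
        assert (dens.counts[visited] == 100).all()

    def test_waytotal_scales_with_seed_voxels(self, small_phantom):
        m = small_phantom["masks"]
        patch = m["seed_patches"][0]
        n_seed = int(patch.sum())
        params = TrackerParams(n_samples=40, angular_sd_deg=0.0, seed=5)
        dens = track_probabilistic(
            small_phantom["maps"], small_phantom["v1"], patch,
            waypoints=[m["plic"], m["peduncle"]],
            params=params,
        )
        assert dens.n_launched == 40 * n_seed
        assert dens.waytotal == 40 * n_seed

    def test_exclusion_plane_blocks_everything(self, small_phantom):
        m = small_phantom["masks"]
        grid = small_phantom["spec"].grid_shape
        seeds = _single_seed(m, grid)
        block = np.zeros(grid, bool)
        block[:, :, grid[2] // 2] = True  # between superior seeds and waypoints
        params = TrackerParams(n_samples=50, angular_sd_deg=0.0, seed=5)
        dens = track_probabilistic(
            small_phantom["maps"], small_phantom["v1"], seeds,
            waypoints=[m["peduncle"]],
            exclusions=[block],
            params=params,
        )
        assert dens.waytotal == 0
        assert dens.counts.sum() == 0

    def test_empty_seed_mask_raises(self, small_phantom):
        grid = small_phantom["spec"].grid_shape
        with pytest.raises(MaskError):
            track_probabilistic(
                small_phantom["maps"], small_phantom["v1"], np.zeros(grid, bool)
            )

    def test_waypoint_and_exclusion_monotonicity(self, small_phantom):
        """Adding a waypoint or an exclusion can only reduce the waytotal."""
        m = small_phantom["masks"]
        patch = m["seed_patches"][1]
        params = TrackerParams(n_samples=60, angular_sd_deg=15.0, seed=21)

        def run(waypoints, exclusions):
            return track_probabilistic(
                small_phantom["maps"], small_phantom["v1"], patch,
                waypoints=waypoints, exclusions=exclusions, params=params,
            ).waytotal

        base = run([], [])
        w1 = run([m["peduncle"]], [])
        w2 = run([m["peduncle"], m["plic"]], [])
        assert base >= w1 >= w2
        e1 = run([m["peduncle"]], [m["midline_exclusion"]])
        grid = small_phantom["spec"].grid_shape
        off_tract = np.zeros(grid, bool)
        off_tract[0:2, :, :] = True
        e2 = run([m["peduncle"]], [m["midline_exclusion"], off_tract])
        assert w1 >= e1 >= e2

    def test_same_seed_identical_different_seed_statistical(self, small_phantom):
        m = small_phantom["masks"]
        patch = m["seed_patches"][2]
        mk = lambda s: track_probabilistic(
            small_phantom["maps"], small_phantom["v1"], patch,
            waypoints=[m["peduncle"]], params=TrackerParams(
                n_samples=400, angular_sd_deg=10.0, seed=s
            ),
        )
        a, b = mk(3), mk(3)
        assert a.waytotal == b.waytotal
        assert np.array_equal(a.counts, b.counts)
        c = mk(4)
        # voxelwise visit fractions agree within binomial sampling error
        sel = (a.counts + c.counts) > 0
        fa_ = a.counts[sel] / a.waytotal
        fc = c.counts[sel] / c.waytotal
        p = (a.counts[sel] + c.counts[sel]) / (a.waytotal + c.waytotal)
        se = np.sqrt(2 * p * (1 - p) / a.waytotal) + 1e-9
        assert np.quantile(np.abs(fa_ - fc) / se, 0.99) < 5.0

    def test_density_matches_high_sample_oracle(self, small_phantom):
        """Independent rerun at 8x samples and a different seed reproduces the
        visit-fraction map (Pearson r > 0.99 on visited voxels)."""
        m = small_phantom["masks"]
        patch = m["seed_patches"][3]
        run = lambda n, s: track_probabilistic(
            small_phantom["maps"], small_phantom["v1"], patch,
            waypoints=[m["plic"], m["peduncle"]],
            exclusions=[m["midline_exclusion"]],
            params=TrackerParams(n_samples=n, angular_sd_deg=10.0, seed=s),
        )
        test = run(250, 11)
        oracle = run(2000, 99)
        sel = (test.counts > 0) | (oracle.counts > 0)
        r = np.corrcoef(
            test.counts[sel] / test.waytotal, oracle.counts[sel] / oracle.waytotal
        )[0, 1]
        assert r > 0.99


class TestNormalizeThreshold:
    def _density(self, counts, waytotal, grid=(2, 2, 2)):
        arr = np.zeros(grid, dtype=np.int64)
        for pos, c in counts.items():
            arr[pos] = c
        return TractDensityMap(counts=arr, waytotal=waytotal, n_launched=waytotal)

    def test_boundary_inclusive(self):
        d = self._density({(0, 0, 0): 50, (1, 0, 0): 49}, 5000)
        mask = normalize_and_threshold_tract(d, 0.01)
        assert mask.data[0, 0, 0]          # 50/5000 = 1% retained (>=)
        assert not mask.data[1, 0, 0]      # 49/5000 excluded

    def test_zero_threshold_keeps_all_visited(self):
        d = self._density({(0, 0, 0): 3, (0, 1, 1): 1}, 10)
        mask = normalize_and_threshold_tract(d, 0.0)
        assert np.array_equal(mask.data, d.counts > 0)

    def test_zero_waytotal_raises(self):
        d = self._density({}, 0)
        with pytest.raises(EmptyTractError):
            normalize_and_threshold_tract(d)


class TestCombine:
    def test_idempotent_union(self, rng):
        m = rng.random((4, 4, 4)) > 0.5
        out = combine_component_tracts([m] * 6)
        assert np.array_equal(out.data, m)

    def test_disjoint_sizes_add(self):
        a = np.zeros((3, 3, 3), bool)
        b = np.zeros((3, 3, 3), bool)
        a[0], b[2] = True, True
        out = combine_component_tracts([a, b])
        assert out.n_voxels == a.sum() + b.sum()

    def test_union_commutes_with_fa_threshold(self, rng):
        fa = rng.random((4, 4, 4))
        maps = ScalarMaps(fa=fa, md=fa, ad=fa, rd=fa, valid=np.ones_like(fa, bool))
        a = rng.random((4, 4, 4)) > 0.4
        b = rng.random((4, 4, 4)) > 0.4
        lhs = apply_fa_threshold(combine_component_tracts([a, b]), maps, 0.2)
        rhs = combine_component_tracts(
            [apply_fa_threshold(a, maps, 0.2), apply_fa_threshold(b, maps, 0.2)]
        )
        assert np.array_equal(lhs.data, rhs.data)

    def test_grid_mismatch_raises(self):
        with pytest.raises(MaskError):
            combine_component_tracts(
                [np.ones((2, 2, 2), bool), np.ones((3, 3, 3), bool)]
            )

    def test_empty_list_raises(self):
        with pytest.raises(MaskError):
            combine_component_tracts([])


class TestFAThreshold:
    def _maps(self, fa):
        fa = np.asarray(fa, float)
        return ScalarMaps(fa=fa, md=fa, ad=fa, rd=fa, valid=np.ones(fa.shape, bool))

    def test_high_fa_mask_unchanged(self):
        mask = np.ones((2, 2, 2), bool)
        out = apply_fa_threshold(mask, self._maps(np.full((2, 2, 2), 0.5)), 0.2)
        assert np.array_equal(out.data, mask)

    def test_all_low_fa_raises(self):
        with pytest.raises(EmptyTractError):
            apply_fa_threshold(
                np.ones((2, 2, 2), bool), self._maps(np.full((2, 2, 2), 0.1)), 0.2
            )

    def test_boundary_is_strict(self):
        fa = np.array([[[0.2, 0.2001]]])
        out = apply_fa_threshold(np.ones((1, 1, 2), bool), self._maps(fa), 0.2)
        assert not out.data[0, 0, 0]   # exactly 0.2 removed
        assert out.data[0, 0, 1]

    def test_lesion_voxels_removed(self):
        fa = np.full((1, 1, 3), 0.5)
        lesion = np.zeros((1, 1, 3), bool)
        lesion[0, 0, 1] = True
        out = apply_fa_threshold(np.ones((1, 1, 3), bool), self._maps(fa), 0.2, lesion)
        assert np.array_equal(out.data[0, 0], [True, False, True])


class TestPeduncleROI:
    def _mask_with_areas(self, areas):
        nz = len(areas)
        m = np.zeros((10, 10, nz), bool)
        for z, a in enumerate(areas):
            flat = np.zeros(100, bool)
            flat[:a] = True
            m[:, :, z] = flat.reshape(10, 10)
        return m

    def test_window_maximizes_area(self):
        # oracle by exhaustive search: [5,9,9,9,5] -> window 1..3 (sum 27)
        m = self._mask_with_areas([5, 9, 9, 9, 5])
        out = peduncle_roi(m, n_slices=3, inferior_max=5)
        assert out.provenance["slices"] == [1, 2, 3]
        assert out.n_voxels == 27

    def test_tie_breaks_most_inferior(self):
        m = self._mask_with_areas([7, 7, 7, 7, 7])
        out = peduncle_roi(m, n_slices=3, inferior_max=5)
        assert out.provenance["slices"] == [0, 1, 2]

    def test_single_slice_is_argmax(self):
        m = self._mask_with_areas([2, 9, 4])
        out = peduncle_roi(m, n_slices=1, inferior_max=3)
        assert out.provenance["slices"] == [1]
        assert out.n_voxels == 9

    def test_too_few_populated_slices(self):
        m = self._mask_with_areas([4, 0, 0, 0, 4])
        with pytest.raises(MaskError):
            peduncle_roi(m, n_slices=3, inferior_max=5)

    def test_exhaustive_window_oracle(self, rng):
        areas = rng.integers(1, 50, size=12)
        m = self._mask_with_areas(list(areas))
        out = peduncle_roi(m, n_slices=3, inferior_max=12)
        sums = [areas[i : i + 3].sum() for i in range(10)]
        best = int(np.argmax(sums))  # argmax returns the first (most inferior) max
        assert out.provenance["slices"] == [best, best + 1, best + 2]


class TestTemplate:
    def test_identity_transform(self, rng):
        m = rng.random((6, 6, 6)) > 0.6
        out = apply_template(m, np.eye(4), m.shape)
        assert np.array_equal(out.data, m)

    def test_pure_translation(self):
        m = np.zeros((8, 8, 8), bool)
        m[2:4, 2:4, 2:4] = True
        t = np.eye(4)
        t[0, 3] = 2.0  # +2 voxels along x
        out = apply_template(m, t, m.shape)
        expected = np.zeros_like(m)
        expected[4:6, 2:4, 2:4] = True
        assert np.array_equal(out.data, expected)

    def test_entirely_outside_raises(self):
        m = np.zeros((4, 4, 4), bool)
        m[0, 0, 0] = True
        t = np.eye(4)
        t[:3, 3] = 50.0
        with pytest.raises(MaskError):
            apply_template(m, t, m.shape)

    def test_zero_jitter_is_deterministic(self):
        from tractrr.tracts import jitter_transform

        rng = np.random.default_rng(0)
        t = jitter_transform(0.0, 1.8, rng)
        assert np.array_equal(t, np.eye(4))


class TestExtractMetrics:
    def _maps(self, fa, md=None):
        fa = np.asarray(fa, float)
        md = fa if md is None else np.asarray(md, float)
        return ScalarMaps(fa=fa, md=md, ad=md, rd=md, valid=np.ones(fa.shape, bool))

    def test_mean_of_two_voxels(self):
        fa = np.array([[[0.4, 0.6]]])
        out = extract_metrics(np.ones((1, 1, 2), bool), self._maps(fa))
        assert out["FA"] == pytest.approx(0.5)
        assert out["voxel_count"] == 2

    def test_single_voxel(self):
        fa = np.array([[[0.37]]])
        out = extract_metrics(np.ones((1, 1, 1), bool), self._maps(fa))
        assert out["FA"] == pytest.approx(0.37)

    def test_union_mean_is_count_weighted(self, rng):
        fa = rng.random((5, 5, 5))
        maps = self._maps(fa)
        a = np.zeros((5, 5, 5), bool)
        b = np.zeros((5, 5, 5), bool)
        a[:2], b[3:] = True, True
        ma = extract_metrics(a, maps)
        mb = extract_metrics(b, maps)
        mu = extract_metrics(a | b, maps)
        na, nb = ma["voxel_count"], mb["voxel_count"]
        assert mu["FA"] == pytest.approx((ma["FA"] * na + mb["FA"] * nb) / (na + nb))

    def test_empty_mask_raises(self):
        with pytest.raises(MaskError):
            extract_metrics(np.zeros((2, 2, 2), bool), self._maps(np.ones((2, 2, 2))))

    def test_mask_io_roundtrip(self, tmp_path, rng):
        from tractrr.tracts import read_mask, write_mask

        m = ROIMask(rng.random((4, 4, 4)) > 0.5, provenance={"approach": "peduncle"})
        write_mask(tmp_path / "m.nii.gz", m, 1.8)
        back = read_mask(tmp_path / "m.nii.gz")
        assert np.array_equal(back.data, m.data)
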