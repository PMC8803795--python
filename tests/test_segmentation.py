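"""Segmentation operators against brute-force voxel-level oracles."""

import numpy as np
import pytest

from petpatterns.segmentation import (
    EmptySegmentationError,
    LesionMask,
    RelativeThresholdUndefinedError,
    apply_fixed_threshold,
    compute_metrics,
    compute_suv_peak,
    exclude_regions,
    majority_vote,
    segment_all_methods,
    segment_relative,
    select_mask,
)
from petpatterns.volume import SuvVolume

from conftest import make_volume, random_phantom


def bfs_component(binary, seed):
    """Independent 26-connectivity flood fill."""
    binary = np.asarray(binary, bool)
    out = np.zeros_like(binary)
    if not binary[seed]:
        return out
    stack = [tuple(seed)]
    out[tuple(seed)] = True
    offsets = [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
    ]
    while stack:
        x, y, z = stack.pop()
        for dx, dy, dz in offsets:
            p = (x + dx, y + dy, z + dz)
            if all(0 <= c < n for c, n in zip(p, binary.shape)):
                if binary[p] and not out[p]:
                    out[p] = True
                    stack.append(p)
    return out


class TestFixedThreshold:
    def test_uniform_sphere_recovers_ground_truth(self, sphere_phantom):
        volume, masks, _, seed = sphere_phantom
        for threshold in (4.0, 2.5):
            mask = apply_fixed_threshold(volume, threshold, seed)
            assert np.array_equal(mask.voxels, masks["lesion_0"])

    def test_two_spheres_only_seeded_component(self):
        values = np.ones((20, 10, 10))
        values[2:5, 4:7, 4:7] = 8.0
        values[12:15, 4:7, 4:7] = 5.0
        vol = make_volume(values)
        mask = apply_fixed_threshold(vol, 4.0, (3, 5, 5))
        assert np.array_equal(mask.voxels, bfs_component(values >= 4.0, (3, 5, 5)))
        assert not mask.voxels[12:15].any()

    def test_seed_below_threshold_raises(self, sphere_phantom):
        volume, _, _, _ = sphere_phantom
        with pytest.raises(EmptySegmentationError, match="below threshold"):
            apply_fixed_threshold(volume, 4.0, (0, 0, 0))

    def test_seed_outside_grid_raises(self, sphere_phantom):
        volume, _, _, _ = sphere_phantom
        with pytest.raises(IndexError):
            apply_fixed_threshold(volume, 4.0, (99, 0, 0))

    def test_threshold_nesting_on_random_phantoms(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            volume, masks, _ = random_phantom(rng)
            seed = tuple(np.argwhere(masks["lesion_0"])[0])
            m40 = apply_fixed_threshold(volume, 4.0, seed)
            m25 = apply_fixed_threshold(volume, 2.5, seed)
            assert not (m40.voxels & ~m25.voxels).any()


class TestSuvPeak:
    def test_uniform_region_peak_equals_value(self, sphere_phantom):
        volume, masks, _, _ = sphere_phantom
        peak = compute_suv_peak(volume, LesionMask(masks["lesion_0"]))
        assert peak == pytest.approx(8.0)

    def test_single_hot_voxel_matches_exhaustive_oracle(self):
        values = np.ones((11, 11, 11))
        values[5, 5, 5] = 10.0
        vol = make_volume(values, spacing=(2.0, 2.0, 2.0))
        mask = np.zeros_like(values, bool)
        mask[5, 5, 5] = True
        got = compute_suv_peak(vol, LesionMask(mask))

        # oracle: place the 1-mL sphere at every mask voxel, average by
        # direct distance scan over the whole grid
        radius = (3 * 1000.0 / (4 * np.pi)) ** (1 / 3)
        best = -np.inf
        for center in np.argwhere(mask):
            acc, cnt = 0.0, 0
            for idx in np.ndindex(values.shape):
                if np.linalg.norm((np.array(idx) - center) * 2.0) <= radius + 1e-9:
                    acc += values[idx]
                    cnt += 1
            best = max(best, acc / cnt)
        assert got == pytest.approx(best)

    def test_peak_never_exceeds_max(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            values = rng.uniform(0, 10, (9, 9, 9))
            vol = make_volume(values)
            mask = np.zeros_like(values, bool)
            mask[2:7, 2:7, 2:7] = True
            assert compute_suv_peak(vol, LesionMask(mask)) <= values.max() + 1e-12

    def test_voxel_larger_than_sphere_rejected(self):
        vol = make_volume(np.ones((4, 4, 4)), spacing=(15.0, 15.0, 15.0))
        mask = np.zeros((4, 4, 4), bool)
        mask[1, 1, 1] = True
        with pytest.raises(ValueError, match="peak sphere"):
            compute_suv_peak(vol, LesionMask(mask))


class TestRelativeThreshold:
    def test_uniform_sphere_41max(self, sphere_phantom):
        volume, masks, _, seed = sphere_phantom
        mask = segment_relative(volume, seed, "PC41MAX")
        # threshold 0.41 * 8.0 = 3.28 sits between background and lesion
        assert np.array_equal(mask.voxels, masks["lesion_0"])

    def test_shoulder_inclusion_matches_brute_force(self):
        # lesion core at 8.0 with attached shoulders at 4.5 and 3.5: the
        # 41%max threshold is 3.28, so PC41MAX keeps both shoulders while
        # SUV4.0 keeps only the 4.5 one
        values = np.ones((10, 10, 10))
        values[4:6, 4:6, 4:6] = 8.0
        values[6, 4:6, 4:6] = 4.5
        values[3, 4:6, 4:6] = 3.5
        vol = make_volume(values)
        m41 = segment_relative(vol, (4, 4, 4), "PC41MAX")
        m40 = apply_fixed_threshold(vol, 4.0, (4, 4, 4))
        assert np.array_equal(m41.voxels, bfs_component(values >= 0.41 * 8.0, (4, 4, 4)))
        assert np.array_equal(m40.voxels, bfs_component(values >= 4.0, (4, 4, 4)))
        assert m41.voxels[6, 4, 4] and m40.voxels[6, 4, 4]
        assert m41.voxels[3, 4, 4] and not m40.voxels[3, 4, 4]

    def test_41max_falls_back_to_local_peak_below_suv4(self):
        # lesion max 3.0 < provisional threshold 4.0: reference comes from
        # the hill-climbed local peak
        values = np.ones((12, 12, 12))
        values[5:8, 5:8, 5:8] = 2.0
        values[6, 6, 6] = 3.0
        vol = make_volume(values)
        mask = segment_relative(vol, (5, 5, 5), "PC41MAX")
        # threshold 1.23: the 2.0/3.0 blob, not the background
        assert np.array_equal(mask.voxels, bfs_component(values >= 0.41 * 3.0, (6, 6, 6)))

    def test_flat_volume_seed_raises(self):
        vol = make_volume(np.ones((8, 8, 8)))
        with pytest.raises(RelativeThresholdUndefinedError):
            segment_relative(vol, (2, 2, 2), "PC41MAX")

    def test_50peak_requires_suv4_region(self):
        vol = make_volume(np.ones((8, 8, 8)) * 2.0)
        with pytest.raises(RelativeThresholdUndefinedError, match="no SUV4"):
            segment_relative(vol, (2, 2, 2), "PC50PEAK")

    def test_50peak_uniform_sphere(self, sphere_phantom):
        volume, masks, _, seed = sphere_phantom
        mask = segment_relative(volume, seed, "PC50PEAK")
        assert np.array_equal(mask.voxels, masks["lesion_0"])

    def test_unknown_mode_rejected(self, sphere_phantom):
        volume, _, _, seed = sphere_phantom
        with pytest.raises(ValueError, match="unknown relative mode"):
            segment_relative(volume, seed, "PC75MAX")


class TestMajorityVote:
    def test_definitional_membership(self):
        grids = [np.zeros((3, 3, 3), bool) for _ in range(4)]
        grids[0][1, 1, 1] = True  # SUV4.0
        grids[2][1, 1, 1] = True  # PC41MAX
        masks = [LesionMask(g, method=m) for g, m in zip(grids, ("SUV4.0", "SUV2.5", "PC41MAX", "PC50PEAK"))]
        assert majority_vote(masks, 2).voxels[1, 1, 1]
        assert not majority_vote(masks, 3).voxels[1, 1, 1]

    def test_identical_masks_fixed_point(self):
        g = np.random.default_rng(0).random((4, 4, 4)) > 0.5
        masks = [LesionMask(g.copy()) for _ in range(4)]
        assert np.array_equal(majority_vote(masks, 2).voxels, g)
        assert np.array_equal(majority_vote(masks, 3).voxels, g)

    def test_random_masks_match_per_voxel_count_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(5):
            grids = [rng.random((6, 6, 6)) > 0.5 for _ in range(4)]
            masks = [LesionMask(g) for g in grids]
            for k in (2, 3):
                got = majority_vote(masks, k).voxels
                for idx in np.ndindex((6, 6, 6)):
                    votes = sum(g[idx] for g in grids)
                    assert got[idx] == (votes >= k)

    def test_wrong_mask_count_rejected(self):
        masks = [LesionMask(np.zeros((2, 2, 2), bool)) for _ in range(3)]
        with pytest.raises(ValueError, match="exactly 4"):
            majority_vote(masks, 2)

    def test_voting_nesting(self):
        rng = np.random.default_rng(3)
        grids = [rng.random((6, 6, 6)) > 0.4 for _ in range(4)]
        masks = [LesionMask(g) for g in grids]
        mv2, mv3 = majority_vote(masks, 2).voxels, majority_vote(masks, 3).voxels
        union = np.logical_or.reduce(grids)
        inter = np.logical_and.reduce(grids)
        assert not (mv3 & ~mv2).any()
        assert not (mv2 & ~union).any()
        assert not (inter & ~mv3).any()


class TestExcludeAndMetrics:
    def test_empty_exclusion_is_identity(self, sphere_phantom):
        volume, masks, _, _ = sphere_phantom
        m = LesionMask(masks["lesion_0"])
        out = exclude_regions(m, np.zeros(volume.shape, bool))
        assert np.array_equal(out.voxels, m.voxels) and not out.fully_excluded

    def test_full_exclusion_flagged(self, sphere_phantom):
        volume, masks, _, _ = sphere_phantom
        out = exclude_regions(LesionMask(masks["lesion_0"]), np.ones(volume.shape, bool))
        assert out.is_empty() and out.fully_excluded

    def test_half_exclusion_matches_set_difference(self, sphere_phantom):
        volume, masks, _, _ = sphere_phantom
        gt = masks["lesion_0"]
        excl = np.zeros(volume.shape, bool)
        excl[:16] = True
        out = exclude_regions(LesionMask(gt), excl)
        assert out.n_voxels == int((gt & ~excl).sum())

    def test_mtv_arithmetic_and_suv_max(self):
        values = np.ones((10, 10, 10))
        mask = np.zeros_like(values, bool)
        mask[:4, :5, :5] = True  # 100 voxels
        values[mask] = 8.0
        metrics = compute_metrics(make_volume(values), LesionMask(mask))
        assert metrics.mtv_ml == pytest.approx(100 * 8 / 1000)
        assert metrics.suv_max == 8.0
        assert metrics.suv_peak <= metrics.suv_max

    def test_suv_max_matches_linear_scan(self):
        rng = np.random.default_rng(9)
        values = rng.uniform(0, 12, (8, 8, 8))
        mask = rng.random((8, 8, 8)) > 0.5
        metrics = compute_metrics(make_volume(values), LesionMask(mask))
        assert metrics.suv_max == max(values[tuple(idx)] for idx in np.argwhere(mask))

    def test_empty_mask_rejected(self):
        with pytest.raises(EmptySegmentationError):
            compute_metrics(make_volume(np.ones((3, 3, 3))), LesionMask(np.zeros((3, 3, 3), bool)))

    def test_mtv_additivity_for_disjoint_masks(self):
        vol = make_volume(np.ones((8, 8, 8)) * 5.0)
        a = np.zeros((8, 8, 8), bool)
        b = np.zeros((8, 8, 8), bool)
        a[:3], b[5:] = True, True
        ma = compute_metrics(vol, LesionMask(a)).mtv_ml
        mb = compute_metrics(vol, LesionMask(b)).mtv_ml
        mu = compute_metrics(vol, LesionMask(a | b)).mtv_ml
        assert ma + mb == pytest.approx(mu)


class TestAllMethods:
    def test_noiseless_sphere_all_methods_exact(self, sphere_phantom):
        volume, masks, _, seed = sphere_phantom
        for name, mask in segment_all_methods(volume, seed).items():
            assert np.array_equal(mask.voxels, masks["lesion_0"]), name

    def test_select_mask_policies(self, sphere_phantom):
        volume, _, _, seed = sphere_phantom
        masks = segment_all_methods(volume, seed)
        assert select_mask(masks).method == "MV2"
        auto = select_mask(masks, policy="auto-smallest-covering")
        core = masks["SUV4.0"].voxels
        assert not (core & ~auto.voxels).any()
        with pytest.raises(ValueError, match="policy"):
            select_mask(masks, policy="nonsense")
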