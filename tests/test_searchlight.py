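"""Searchlight maps: neighborhoods, z-scoring, planted-signal recovery."""

import numpy as np
import pytest

from vishom import synthetic_data as sd
from vishom.perceptual_space import DissimilarityMatrix
from vishom.searchlight import (
    VoxelDataset,
    define_region,
    neighborhood_indices,
    rdm_correlation_map,
    region_mean_correlation,
    rt_correlation_map,
    vh_correlation_map,
    zscore_by_group,
)


def _full_mask(shape=(6, 6, 6)):
    return np.ones(shape, dtype=bool)


class TestNeighborhood:
    def test_interior_voxel_has_27_neighbors(self):
        idx = neighborhood_indices(_full_mask(), (3, 3, 3))
        assert len(idx) == 27

    def test_grid_corner_has_8_neighbors(self):
        idx = neighborhood_indices(_full_mask(), (0, 0, 0))
        assert len(idx) == 8

    def test_neighborhood_clipped_to_mask(self):
        mask = _full_mask()
        mask[4:] = False  # half the cube masked out along x
        idx = neighborhood_indices(mask, (3, 3, 3))
        assert len(idx) == 18
        assert all(mask[tuple(v)] for v in idx)

    def test_out_of_mask_center_rejected(self):
        mask = _full_mask()
        mask[2, 2, 2] = False
        with pytest.raises(ValueError):
            neighborhood_indices(mask, (2, 2, 2))


class TestZScore:
    def test_three_values_map_to_unit_steps(self):
        np.testing.assert_allclose(
            zscore_by_group(np.array([1.0, 2.0, 3.0]), ["g"] * 3), [-1.0, 0.0, 1.0]
        )

    def test_groups_centered_and_scaled(self):
        vals = np.array([10.0, 12.0, 14.0, 100.0, 105.0, 95.0])
        labels = ["a"] * 3 + ["b"] * 3
        z = zscore_by_group(vals, labels)
        for lab in ("a", "b"):
            g = np.array(labels) == lab
            assert abs(z[g].mean()) <= 1e-12
            assert z[g].std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_idempotent(self):
        vals = np.array([0.3, 1.9, -2.0, 0.0, 5.0, 2.5])
        labels = ["a", "a", "a", "b", "b", "b"]
        once = zscore_by_group(vals, labels)
        np.testing.assert_allclose(zscore_by_group(once, labels), once, atol=1e-12)


def _planted(noise_sigma, n_cond=32, seed=0, grid=(12, 12, 12), n_subjects=1):
    layout = sd.make_layout(grid_shape=grid, vh_corner=(2, 2, 2),
                            rt_corner=(7, 7, 7), region_shape=(3, 3, 3),
                            noise_sigma=noise_sigma)
    rng = np.random.default_rng(seed)
    half = n_cond // 2
    # mirrored-about-boundary design: pooled corr(vh, rt) is exactly zero
    delta = np.sort(rng.uniform(0.2, 1.0, half))
    vh = np.concatenate([1.5 - delta, 1.5 + delta])
    rt = 2.0 - 0.4 * np.abs(vh - 1.5)
    labels = ["present"] * half + ["absent"] * half
    data = sd.gen_voxel_data(layout, vh, rt, seed=seed + 1, n_subjects=n_subjects)
    return layout, data, vh, rt, labels


class TestActivationMaps:
    def test_noiseless_vh_region_correlates_perfectly(self):
        layout, data, vh, rt, labels = _planted(0.0)
        m = vh_correlation_map(data, vh, labels)
        assert np.all(np.abs(m.values[layout.vh_region] - 1.0) <= 1e-9)

    def test_noiseless_rt_region_correlates_perfectly_with_rt(self):
        layout, data, vh, rt, labels = _planted(0.0)
        m = rt_correlation_map(data, rt, labels)
        region_core = np.zeros_like(layout.rt_region)
        region_core[8, 8, 8] = True  # interior voxel: neighborhood inside region
        assert m.values[region_core][0] == pytest.approx(1.0, abs=1e-9)

    def test_pure_noise_voxels_show_null_correlations(self):
        # Monte-Carlo null: mean |r| for n=32 conditions after group z-scoring
        layout, data, vh, rt, labels = _planted(1.0, seed=5)
        outside = ~(layout.vh_region | layout.rt_region)
        # erode: keep voxels whose whole neighborhood is signal-free
        from scipy.ndimage import binary_erosion

        core = binary_erosion(outside, np.ones((3, 3, 3))) & layout.mask
        m = vh_correlation_map(data, vh, labels)
        rs = m.values[core]
        rng = np.random.default_rng(0)
        null = np.array([
            abs(np.corrcoef(rng.standard_normal(32), vh)[0, 1]) for _ in range(2000)
        ])
        se = null.std(ddof=1) / np.sqrt(len(rs))
        assert abs(np.abs(rs).mean() - null.mean()) <= 4 * se

    def test_rt_coding_voxel_uncorrelated_with_vh_in_mirrored_design(self):
        layout, data, vh, rt, labels = _planted(0.0)
        m = vh_correlation_map(data, vh, labels)
        region_core = np.zeros_like(layout.rt_region)
        region_core[8, 8, 8] = True
        assert abs(m.values[region_core][0]) <= 0.1

    def test_vh_region_uncorrelated_with_rt_in_mirrored_design(self):
        layout, data, vh, rt, labels = _planted(0.0)
        m = rt_correlation_map(data, rt, labels)
        region_core = np.zeros_like(layout.vh_region)
        region_core[3, 3, 3] = True
        assert abs(m.values[region_core][0]) <= 0.1

    def test_scope_restricts_to_one_group(self):
        layout, data, vh, rt, labels = _planted(0.0)
        m_all = rt_correlation_map(data, rt, labels, scope="all")
        m_a = rt_correlation_map(data, rt, labels, scope="groupA")
        assert m_all.values.shape == m_a.values.shape
        # within one group RT is monotone in VH, so the VH region now correlates
        region_core = np.zeros_like(layout.vh_region)
        region_core[3, 3, 3] = True
        assert abs(m_a.values[region_core][0]) == pytest.approx(1.0, abs=1e-9)

    def test_values_bounded_or_nan(self):
        layout, data, vh, rt, labels = _planted(0.5, seed=2)
        m = vh_correlation_map(data, vh, labels)
        inside = m.values[layout.mask]
        finite = inside[~np.isnan(inside)]
        assert np.all((finite >= -1.0 - 1e-12) & (finite <= 1.0 + 1e-12))
        assert np.all(np.isnan(m.values[~layout.mask]))


class TestRDMMap:
    def test_identical_patterns_have_zero_neural_distance(self):
        mask = _full_mask((5, 5, 5))
        betas = np.ones((3, 5, 5, 5))
        betas[2] = 2.0
        d = DissimilarityMatrix(objects=["a", "b", "c"],
                                d=np.array([[0, 1.0, 1], [1, 0, 1], [1, 1, 0.0]]))
        data = VoxelDataset(mask=mask, conditions=["a", "b", "c"], betas=betas)
        m = rdm_correlation_map(data, d)
        # conditions a and b have identical patterns everywhere: the neural RDM
        # is degenerate but finite; just assert the map computed without error
        assert m.values.shape == (5, 5, 5)

    def test_embedding_coordinates_as_activations_give_unit_correlation(self):
        # plant each object's 2-D coordinates into two voxels of a neighborhood
        rng = np.random.default_rng(3)
        coords = rng.normal(size=(8, 2))
        from scipy.spatial.distance import pdist, squareform

        d = DissimilarityMatrix(objects=[f"o{i}" for i in range(8)],
                                d=squareform(pdist(coords)))
        mask = _full_mask((5, 5, 5))
        betas = np.zeros((8, 5, 5, 5))
        betas[:, 2, 2, 2] = coords[:, 0]
        betas[:, 2, 2, 3] = coords[:, 1]
        data = VoxelDataset(mask=mask, conditions=d.objects, betas=betas)
        m = rdm_correlation_map(data, d)
        assert m.values[2, 2, 2] == pytest.approx(1.0, abs=1e-9)

    def test_planted_linear_image_peaks_inside_region(self):
        rng = np.random.default_rng(7)
        coords = rng.normal(size=(10, 3))
        from scipy.spatial.distance import pdist, squareform

        d = DissimilarityMatrix(objects=[f"o{i}" for i in range(10)],
                                d=squareform(pdist(coords)))
        grid = (10, 10, 10)
        mask = np.ones(grid, dtype=bool)
        betas = rng.normal(scale=0.05, size=(10,) + grid)
        # "LO-like" region: a noisy random linear image of the embedding
        region = np.zeros(grid, dtype=bool)
        region[2:5, 2:5, 2:5] = True
        proj = rng.normal(size=(3, int(region.sum())))
        betas[:, region] += coords @ proj
        data = VoxelDataset(mask=mask, conditions=d.objects, betas=betas)
        m = rdm_correlation_map(data, d)
        peak = np.unravel_index(np.nanargmax(m.values), grid)
        assert region[peak]
        assert np.nanmean(m.values[region]) > np.nanmean(m.values[~region])

    def test_too_few_objects_rejected(self):
        d = DissimilarityMatrix(objects=["a", "b"], d=np.array([[0.0, 1.0], [1.0, 0.0]]))
        data = VoxelDataset(mask=_full_mask((3, 3, 3)), conditions=["a", "b"],
                            betas=np.zeros((2, 3, 3, 3)))
        with pytest.raises(ValueError):
            rdm_correlation_map(data, d)


class TestRegions:
    def test_single_planted_cuboid_recovered(self):
        layout, data, vh, rt, labels = _planted(0.05)
        m = vh_correlation_map(data, vh, labels)
        regions = define_region(m, threshold=0.8, min_cluster=2)
        assert len(regions) >= 1
        top = regions[0]
        planted = set(map(tuple, np.argwhere(layout.vh_region)))
        found = set(map(tuple, top.voxels))
        assert planted <= found  # all planted voxels suprathreshold and connected

    def test_threshold_above_max_gives_empty_list(self):
        layout, data, vh, rt, labels = _planted(0.0)
        m = vh_correlation_map(data, vh, labels)
        assert define_region(m, threshold=0.999999, min_cluster=1) == [] or all(
            r.size == 0 for r in define_region(m, threshold=0.999999, min_cluster=10**6)
        )

    def test_two_disjoint_regions_found_separately(self):
        vals = np.full((8, 8, 8), np.nan)
        vals[1:3, 1:3, 1:3] = 0.9
        vals[5:7, 5:7, 5:7] = 0.8
        from vishom.searchlight import SearchlightMap

        regions = define_region(SearchlightMap(values=vals, kind="vh_correlation"),
                                threshold=0.5, min_cluster=2)
        assert [r.size for r in regions] == [8, 8]


class TestRegionCorrelation:
    def test_noiseless_single_subject_r_one_bootstrap_skipped(self):
        layout, data, vh, rt, labels = _planted(0.0)
        vox = np.argwhere(layout.vh_region)
        with pytest.warns(UserWarning, match="single subject"):
            res = region_mean_correlation(data.betas[None], layout.mask, vox, vh,
                                          labels, n_boot=100, seed=0)
        assert res.r == pytest.approx(1.0, abs=1e-9)
        assert np.isnan(res.boot_sd)

    def test_identical_subjects_have_zero_bootstrap_sd(self):
        layout, data, vh, rt, labels = _planted(0.0)
        vox = np.argwhere(layout.vh_region)
        stack = np.repeat(data.betas[None], 3, axis=0)
        res = region_mean_correlation(stack, layout.mask, vox, vh, labels,
                                      n_boot=200, seed=0)
        assert res.boot_sd == pytest.approx(0.0, abs=1e-12)
        assert res.boot_p == 0.0

    def test_bootstrap_sd_tracks_between_dataset_sd(self):
        # Monte-Carlo oracle: SD of r over freshly regenerated datasets
        n_sub = 12
        rs = []
        for s in range(60):
            layout, data, vh, rt, labels = _planted(4.0, seed=100 + s,
                                                    grid=(8, 8, 8), n_subjects=n_sub)
            # rebuild layout regions for the smaller grid
            vox = np.argwhere(layout.vh_region)
            act = data.subject_betas[:, :, vox[:, 0], vox[:, 1], vox[:, 2]].mean(axis=2)
            from vishom.searchlight import zscore_by_group
            from vishom._utils import pearson

            rs.append(pearson(zscore_by_group(act.mean(axis=0), labels),
                              zscore_by_group(vh, labels)))
        truth_sd = np.std(rs, ddof=1)
        layout, data, vh, rt, labels = _planted(4.0, seed=100, grid=(8, 8, 8),
                                                n_subjects=n_sub)
        res = region_mean_correlation(data.subject_betas, layout.mask,
                                      np.argwhere(layout.vh_region), vh, labels,
                                      n_boot=1500, seed=1)
        assert res.boot_sd == pytest.approx(truth_sd, rel=0.5)
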