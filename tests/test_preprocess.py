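"""Normalization, windowing, point-cloud filters, image standardization
and plant-level splitting — including brute-force oracles for the
point-cloud operations."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from edfm.errors import DegenerateChannelError, InvalidArgumentError
from edfm.preprocess import (
    apply_zscore,
    downsample_to_count,
    fit_zscore,
    invert_zscore,
    sliding_windows,
    smooth_series,
    sor_filter,
    split_plants,
    standardize_image,
    voxel_downsample,
)


class TestZscore:
    def test_population_sd_of_123(self):
        stats = fit_zscore(np.array([[1.0], [2.0], [3.0]]))
        assert stats.mu[0] == pytest.approx(2.0)
        assert stats.sigma[0] == pytest.approx(0.8165, abs=1e-4)
        assert apply_zscore(np.array([3.0]), stats)[0] == pytest.approx(1.2247, abs=1e-4)

    def test_constant_channel_raises_with_name(self):
        with pytest.raises(DegenerateChannelError, match="temp"):
            fit_zscore(np.array([[2.0], [2.0], [2.0]]), channels=("temp",))

    def test_mu_maps_to_zero_and_mu_plus_sigma_to_one(self):
        stats = fit_zscore(np.array([[1.0], [2.0], [3.0]]))
        assert apply_zscore(stats.mu, stats)[0] == pytest.approx(0.0)
        assert apply_zscore(stats.mu + stats.sigma, stats)[0] == pytest.approx(1.0)

    def test_train_transform_is_standardized(self):
        rng = np.random.default_rng(0)
        x = rng.normal(3.0, 2.5, size=(200, 4))
        z = apply_zscore(x, fit_zscore(x))
        assert np.allclose(z.mean(axis=0), 0, atol=1e-12)
        assert np.allclose(z.std(axis=0), 1, atol=1e-12)

    @given(st.integers(0, 2**31 - 1))
    def test_roundtrip_identity(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(20, 3)) * [1, 10, 100]
        stats = fit_zscore(x)
        assert np.allclose(invert_zscore(apply_zscore(x, stats), stats), x, atol=1e-12)

    def test_channel_mismatch(self):
        stats = fit_zscore(np.array([[1.0, 2.0], [3.0, 4.0]]))
        with pytest.raises(InvalidArgumentError):
            apply_zscore(np.zeros(3), stats)


class TestWindows:
    @pytest.mark.parametrize(
        "n, width, stride, expected",
        [(7, 7, 1, 1), (10, 7, 1, 4), (6, 7, 1, 0), (10, 3, 2, 4)],
    )
    def test_count_formula(self, n, width, stride, expected):
        wins = sliding_windows(np.arange(n), width, stride)
        assert len(wins) == expected
        for w in wins:
            assert len(w) == width

    def test_windows_are_contiguous_and_ordered(self):
        wins = sliding_windows(np.arange(10), 4, 2)
        assert [w[0] for w in wins] == [0, 2, 4, 6]

    def test_trailing_mean_smoother(self):
        out = smooth_series(np.array([1.0, 2.0, 3.0, 4.0]), width=2)
        assert np.allclose(out, [1.0, 1.5, 2.5, 3.5])


def _brute_sor(pts, k, ratio):
    d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
    np.fill_diagonal(d, np.inf)
    mean_d = np.sort(d, axis=1)[:, :k].mean(axis=1)
    thr = mean_d.mean() + ratio * mean_d.std()
    return np.flatnonzero(mean_d > thr)


class TestSorFilter:
    def test_grid_with_far_outlier(self):
        grid = np.array(
            [[i, j, k] for i in range(3) for j in range(3) for k in range(3)], float
        )
        cloud = np.vstack([grid, [[100.0, 100.0, 100.0]]])
        filtered, removed = sor_filter(cloud, k_neighbors=8, std_ratio=2.0)
        assert list(removed) == [27]
        assert len(filtered) == 27

    def test_equal_spacing_cloud_keeps_everything(self):
        # unit-spaced collinear points: every nearest-neighbour distance is
        # exactly 1, so sd(d) = 0 and the threshold keeps everything
        line = np.column_stack([np.arange(24.0), np.zeros(24), np.zeros(24)])
        _, removed = sor_filter(line, k_neighbors=1, std_ratio=2.0)
        assert removed.size == 0

    def test_too_few_points_rejected(self):
        with pytest.raises(InvalidArgumentError):
            sor_filter(np.zeros((5, 3)), k_neighbors=8)

    @given(st.integers(0, 2**31 - 1))
    def test_matches_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(60, 3))
        pts[:5] += 8.0  # a displaced clump
        _, removed = sor_filter(pts, k_neighbors=6, std_ratio=1.5)
        assert set(removed) == set(_brute_sor(pts, 6, 1.5))


def _brute_voxel(pts, size):
    origin = pts.min(axis=0)
    cells = {}
    for p in pts:
        key = tuple(np.floor((p - origin) / size).astype(int))
        cells.setdefault(key, []).append(p)
    return np.array([np.mean(v, axis=0) for v in cells.values()])


def _sorted_rows(a):
    return a[np.lexsort(a.T)]


class TestVoxelDownsample:
    def test_single_voxel_centroid(self):
        pts = np.random.default_rng(1).random((50, 3)) * 0.01
        out = voxel_downsample(pts, 1.0)
        assert out.shape == (1, 3)
        assert np.allclose(out[0], pts.mean(axis=0))

    def test_unit_cube_corners_stay_distinct(self):
        corners = np.array(
            [[i, j, k] for i in (0, 1) for j in (0, 1) for k in (0, 1)], float
        )
        out = voxel_downsample(corners, 0.6)
        assert len(out) == 8
        assert np.allclose(_sorted_rows(out), _sorted_rows(corners))

    @given(st.integers(0, 2**31 - 1))
    def test_matches_hashmap_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.random((150, 3)) * 3
        out = voxel_downsample(pts, 0.5)
        ref = _brute_voxel(pts, 0.5)
        assert np.allclose(_sorted_rows(out), _sorted_rows(ref))

    @given(st.integers(0, 2**31 - 1))
    def test_monotone_in_voxel_size(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.random((120, 3))
        counts = [len(voxel_downsample(pts, s)) for s in (0.05, 0.1, 0.2, 0.5, 1.0)]
        assert counts == sorted(counts, reverse=True)

    def test_invalid_size(self):
        with pytest.raises(InvalidArgumentError):
            voxel_downsample(np.zeros((4, 3)), 0.0)


class TestDownsampleToCount:
    def test_small_cloud_unchanged(self):
        pts = np.random.default_rng(0).random((100, 3))
        assert np.array_equal(downsample_to_count(pts, 100), pts)

    def test_dense_plant_to_ten_thousand(self):
        from edfm.synthdata import SyntheticPlantSpec, generate_point_cloud

        spec = SyntheticPlantSpec(points_per_leaf=10000, points_per_internode=3000,
                                  noise_sd=0.3, seed=4)
        pts, _ = generate_point_cloud(spec)
        assert len(pts) >= 100_000
        out = downsample_to_count(pts, 10_000)
        assert 9_500 <= len(out) <= 10_500


class TestStandardizeImage:
    def test_output_shape_and_range(self):
        img = np.random.default_rng(0).integers(0, 256, (480, 640, 3), dtype=np.uint8)
        out = standardize_image(img)
        assert out.shape == (224, 224, 3)
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_constant_255_maps_to_one(self):
        out = standardize_image(np.full((100, 100, 3), 255, dtype=np.uint8))
        assert np.allclose(out, 1.0)

    def test_zero_224_identity(self):
        out = standardize_image(np.zeros((224, 224, 3), dtype=np.uint8))
        assert np.array_equal(out, np.zeros((224, 224, 3)))

    def test_idempotent_on_standardized(self):
        img = np.random.default_rng(1).integers(0, 256, (300, 200, 3), dtype=np.uint8)
        once = standardize_image(img)
        twice = standardize_image(once)
        assert np.allclose(once, twice, atol=1e-6)

    def test_empty_rejected(self):
        with pytest.raises(InvalidArgumentError):
            standardize_image(np.zeros((0, 10, 3)))


class TestSplitPlants:
    def test_ten_plants_six_two_two(self):
        split = split_plants([f"p{i}" for i in range(10)], seed=0)
        sizes = {lab: len(split.ids(lab)) for lab in ("train", "validation", "test")}
        assert sizes == {"train": 6, "validation": 2, "test": 2}

    def test_same_seed_identical(self):
        ids = [f"p{i}" for i in range(23)]
        assert split_plants(ids, seed=5).assignment == split_plants(ids, seed=5).assignment

    def test_duplicates_rejected(self):
        with pytest.raises(InvalidArgumentError):
            split_plants(["a", "a", "b", "c", "d"])

    def test_no_leakage_many_seeds(self):
        ids = [f"p{i}" for i in range(17)]
        for seed in range(1000):
            a = split_plants(ids, seed=seed).assignment
            assert set(a) == set(ids)  # exhaustive
            assert len(a) == len(ids)  # one partition per plant, disjoint by dict
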