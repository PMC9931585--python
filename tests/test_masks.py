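"""Mask construction: each step against an independent brute-force oracle."""

import itertools

import numpy as np
import pytest

from imctme import (
    MaskParams,
    adaptive_refine,
    build_marker_mask,
    median_smooth,
    quantize_levels,
    remove_small_blobs,
    select_foreground,
)


def median_oracle(raster, window):
    """Per-pixel median with edge replication, computed naively."""
    h, w = raster.shape
    r = window // 2
    pad = np.pad(raster, r, mode="edge")
    out = np.empty_like(raster)
    for i in range(h):
        for j in range(w):
            out[i, j] = np.median(pad[i : i + window, j : j + window])
    return out


def lloyd_1d_oracle(values, k, n_starts=50, seed=0):
    """1-D k-means by Lloyd iteration to convergence, best of n_starts."""
    rng = np.random.default_rng(seed)
    best, best_sse = None, np.inf
    for _ in range(n_starts):
        centers = rng.choice(values, size=k, replace=False).astype(float)
        for _ in range(500):
            assign = np.argmin(np.abs(values[:, None] - centers[None, :]), axis=1)
            new = np.array(
                [values[assign == c].mean() if (assign == c).any() else centers[c] for c in range(k)]
            )
            if np.allclose(new, centers):
                break
            centers = new
        sse = ((values - centers[assign]) ** 2).sum()
        if sse < best_sse - 1e-12:
            best_sse, best = sse, (centers.copy(), assign.copy())
    centers, assign = best
    order = np.argsort(centers)
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(1, k + 1)
    return relabel[assign]


def flood_fill_components(mask):
    """8-connected components by BFS (oracle for blob removal)."""
    comp = np.zeros(mask.shape, dtype=int)
    cur = 0
    for i, j in zip(*np.nonzero(mask)):
        if comp[i, j]:
            continue
        cur += 1
        stack = [(i, j)]
        comp[i, j] = cur
        while stack:
            a, b = stack.pop()
            for da, db in itertools.product((-1, 0, 1), repeat=2):
                x, y = a + da, b + db
                if (
                    0 <= x < mask.shape[0]
                    and 0 <= y < mask.shape[1]
                    and mask[x, y]
                    and not comp[x, y]
                ):
                    comp[x, y] = cur
                    stack.append((x, y))
    return comp, cur


class TestMedianSmooth:
    def test_constant_raster_unchanged(self):
        img = np.full((9, 9), 7.0)
        assert np.array_equal(median_smooth(img, 3), img)

    def test_median_kills_singleton(self):
        img = np.zeros((7, 7))
        img[3, 3] = 100.0
        assert median_smooth(img, 3).max() == 0.0

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            median_smooth(np.zeros((4, 4)), 4)

    @pytest.mark.parametrize("window", [3, 5])
    def test_matches_brute_force(self, rng, window):
        for _ in range(20):
            img = rng.integers(0, 30, size=(5, 5)).astype(float)
            assert np.array_equal(median_smooth(img, window), median_oracle(img, window))


class TestQuantizeLevels:
    def test_two_valued_raster(self):
        img = np.where(np.arange(64).reshape(8, 8) % 2 == 0, 0.0, 100.0)
        lv = quantize_levels(img, 2)
        assert set(lv[img == 0.0].ravel()) == {1}
        assert set(lv[img == 100.0].ravel()) == {2}

    def test_constant_raster_collapses_with_warning(self):
        with pytest.warns(UserWarning, match="distinct"):
            lv = quantize_levels(np.full((6, 6), 3.0), 6)
        assert set(lv.ravel()) == {1}

    def test_trimodal_matches_lloyd_oracle(self, rng):
        centers = [5.0, 60.0, 200.0]
        img = np.concatenate(
            [rng.normal(c, 4.0, size=64 * 64 // 3 + 1) for c in centers]
        )[: 64 * 64].round().reshape(64, 64)
        lv = quantize_levels(img, 3)
        oracle = lloyd_1d_oracle(img.ravel(), 3).reshape(64, 64)
        assert np.array_equal(lv, oracle)

    def test_random_rasters_match_lloyd_oracle(self, rng):
        # exact equivalence of the DP solution with multistart Lloyd
        for i in range(10):
            img = rng.integers(0, 25, size=(16, 16)).astype(float)
            lv = quantize_levels(img, 4)
            oracle = lloyd_1d_oracle(img.ravel(), 4, seed=i).reshape(16, 16)
            assert np.array_equal(lv, oracle)

    def test_seed_irrelevant(self, rng):
        img = rng.random((32, 32))
        assert np.array_equal(quantize_levels(img, 6, seed=0), quantize_levels(img, 6, seed=99))


class TestSelectForeground:
    def test_saturation_all_foreground(self, rng):
        lv = rng.integers(1, 7, size=(10, 10))
        assert select_foreground(lv, 6).all()

    def test_top_level_only(self, rng):
        lv = rng.integers(1, 7, size=(10, 10))
        lv[0, 0] = 6
        assert np.array_equal(select_foreground(lv, 1), lv == 6)

    def test_union_of_top_two(self, rng):
        lv = rng.integers(1, 4, size=(12, 12))
        lv[0, :2] = [3, 2]
        assert np.array_equal(select_foreground(lv, 2), lv >= 2)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            select_foreground(np.ones((3, 3), dtype=int) * 2, 5)


class TestRemoveSmallBlobs:
    def test_min_area_zero_is_identity(self, rng):
        m = rng.random((20, 20)) < 0.4
        assert np.array_equal(remove_small_blobs(m, 0), m)

    def test_keeps_only_large_blob(self):
        m = np.zeros((12, 12), dtype=bool)
        m[1, 1:4] = True  # area 3
        m[6:8, 6:11] = True  # area 10
        out = remove_small_blobs(m, 5)
        assert out.sum() == 10 and not out[1, 1]

    def test_matches_flood_fill_oracle(self, rng):
        for _ in range(20):
            m = rng.random((24, 24)) < 0.35
            comp, ncomp = flood_fill_components(m)
            sizes = np.bincount(comp.ravel())
            expected = np.isin(comp, np.flatnonzero(sizes >= 4)) & (comp > 0)
            assert np.array_equal(remove_small_blobs(m, 4), expected)

    def test_idempotent(self, rng):
        m = rng.random((30, 30)) < 0.3
        once = remove_small_blobs(m, 6)
        assert np.array_equal(remove_small_blobs(once, 6), once)


class TestAdaptiveRefine:
    def test_uniform_channel_never_adds(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[2:5, 2:5] = True
        out = adaptive_refine(np.full((10, 10), 4.0), mask)
        assert not (out & ~mask).any()

    def test_bright_blob_retained(self):
        img = np.full((20, 20), 1.0)
        img[8:12, 8:12] = 50.0
        mask = img > 10
        out = adaptive_refine(img, mask, 0.4)
        assert out[9, 9]

    def test_output_subset_of_input(self, rng):
        for _ in range(100):
            img = rng.random((16, 16)) * 10
            mask = rng.random((16, 16)) < 0.5
            out = adaptive_refine(img, mask, rng.random())
            assert not (out & ~mask).any()


class TestBuildMarkerMask:
    def test_four_step_composition_when_merge_disabled(self, rng):
        img = rng.integers(0, 40, size=(32, 32)).astype(float)
        params = MaskParams(foreground_level=2, min_blob_area=3, adaptive_merge=False)
        got = build_marker_mask(img, params).mask
        smooth = median_smooth(img, 3)
        lv = quantize_levels(smooth, 6)
        expected = remove_small_blobs(select_foreground(lv, 2), 3)
        assert np.array_equal(got, expected)

    def test_deterministic(self, rng):
        img = rng.random((40, 40)) * 20
        params = MaskParams()
        a = build_marker_mask(img, params, seed=1).mask
        b = build_marker_mask(img, params, seed=1).mask
        assert np.array_equal(a, b)

    def test_constant_channel_gives_empty_mask(self):
        with pytest.warns(UserWarning):
            out = build_marker_mask(np.full((16, 16), 2.0), MaskParams())
        assert not out.mask.any()


def test_mask_fidelity_on_planted_signal():
    """With per-marker curated parameters, masks recover >=95% of
    on-target cell pixels and <5% background on synthetic channels."""
    import imctme as it

    panel, rules, props, targets = it.simple_conditions(2)
    spec = it.SyntheticSpec(
        type_proportions=props, marker_targets=targets, cell_density=8.0,
        cell_radius=8, min_separation=18.0,
    )
    curated = MaskParams(foreground_level=5, min_blob_area=2)
    core = it.generate_core(spec, seed=4)
    lab = core.seg.label_raster
    types = core.truth.df["lineage"].to_numpy()
    for marker, (t,) in targets.items():
        on_px = np.concatenate([[False], types == t])[lab]
        mask = build_marker_mask(core.stack[marker], curated, marker=marker).mask
        assert mask[on_px].mean() >= 0.95
        assert mask[~on_px].mean() <= 0.05
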