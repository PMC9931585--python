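"""Pairwise interaction/avoidance testing: geometry oracles, exact
enumeration on tiny cores, and invariances."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

import imctme as it


def _seg_from_pixels(pixel_lists, shape=(40, 40)):
    lab = np.zeros(shape, dtype=int)
    for cid, pixels in enumerate(pixel_lists, start=1):
        for r, c in pixels:
            lab[r, c] = cid
    return it.SegmentationMap("core", lab)


class TestAdjacency:
    def test_six_pixels_apart_is_edge(self):
        seg = _seg_from_pixels([[(10, 10)], [(10, 16)]])
        g = it.build_adjacency(seg, d=6, rule="boundary")
        assert g.edges == {(1, 2)}

    def test_seven_pixels_apart_is_not(self):
        seg = _seg_from_pixels([[(10, 10)], [(10, 17)]])
        assert it.build_adjacency(seg, d=6).edges == set()

    def test_boundary_rule_uses_mask_distance(self):
        # centroids 10 apart, but masks reach within 6
        seg = _seg_from_pixels([[(5, 5), (5, 9)], [(5, 15), (5, 19)]])
        assert it.build_adjacency(seg, d=6, rule="boundary").edges == {(1, 2)}
        assert it.build_adjacency(seg, d=6, rule="centroid").edges == set()

    def test_matches_all_pairs_brute_force(self, rng):
        pts = rng.integers(0, 60, size=(30, 2))
        pts = np.unique(pts, axis=0)
        seg = _seg_from_pixels([[tuple(p)] for p in pts], shape=(60, 60))
        g = it.build_adjacency(seg, d=6, rule="boundary")
        expected = set()
        for i in range(len(pts)):
            for j in range(i + 1, len(pts)):
                if math.dist(pts[i], pts[j]) <= 6:
                    expected.add((i + 1, j + 1))
        assert g.edges == expected


def exhaustive_pvalues(graph, labels, type_order):
    """Exact permutation p-values by enumerating every label assignment."""
    from imctme.interactions import _pair_stats, _TIE_EPS
    from scipy import sparse

    ids = list(graph.cell_ids)
    n = len(ids)
    t = len(type_order)
    tindex = {name: k for k, name in enumerate(type_order)}
    y_obs = np.array([tindex[labels[c]] for c in ids])
    pos = {c: k for k, c in enumerate(ids)}
    rows, cols = [], []
    for a, b in graph.edges:
        rows += [pos[a], pos[b]]
        cols += [pos[b], pos[a]]
    adj = sparse.coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n)).tocsr()
    n_per = np.bincount(y_obs, minlength=t).astype(float)

    def stats(y):
        m = np.zeros((n, t))
        m[np.arange(n), y] = 1.0
        return _pair_stats(m, adj, n_per)

    obs = stats(y_obs)
    ge = np.zeros((t, t))
    le = np.zeros((t, t))
    total = 0
    for perm in set(itertools.permutations(y_obs)):
        s = stats(np.array(perm))
        ge += s >= obs - _TIE_EPS
        le += s <= obs + _TIE_EPS
        total += 1
    return ge / total, le / total


class TestInteractionTest:
    def test_segregated_blocks_called_avoidance(self):
        # types A and B in far-apart dense blocks: A-B avoidance
        pixels = []
        labels = {}
        cid = 0
        for r in range(4):
            for c in range(4):
                cid += 1
                pixels.append([(2 + 2 * r, 2 + 2 * c)])
                labels[cid] = "A"
        for r in range(4):
            for c in range(4):
                cid += 1
                pixels.append([(30 + 2 * r, 30 + 2 * c)])
                labels[cid] = "B"
        seg = _seg_from_pixels(pixels)
        g = it.build_adjacency(seg, d=6)
        res = it.interaction_test(g, pd.Series(labels), n_perm=1000, seed=0)
        i, j = res.types.index("A"), res.types.index("B")
        assert res.call[i, j] == "avoidance"
        assert res.p_avoid[i, j] <= 0.01

    def test_permutation_close_to_exhaustive_on_tiny_core(self, rng):
        # <= 7 cells: enumeration over all label permutations is exact
        pts = [(3, 3), (3, 8), (8, 5), (15, 15), (18, 12), (20, 20), (3, 20)]
        seg = _seg_from_pixels([[p] for p in pts], shape=(25, 25))
        g = it.build_adjacency(seg, d=6)
        labels = pd.Series(
            ["A", "A", "B", "B", "A", "B", "B"], index=range(1, 8)
        )
        # 4,000 permutations keep the Monte-Carlo s.e. (~0.008 at p=0.5)
        # well inside the 0.02 comparison tolerance
        order = ("A", "B")
        res = it.interaction_test(g, labels, n_perm=4000, seed=3, type_order=order)
        ge, le = exhaustive_pvalues(g, labels, order)
        assert np.all(np.abs(res.p_interact - ge) <= 0.02)
        assert np.all(np.abs(res.p_avoid - le) <= 0.02)

    def test_add_one_lower_bound(self, noisy_core, noisy_core_table):
        sub = noisy_core_table.df
        g = it.build_adjacency(noisy_core.seg, d=6)
        types = pd.Series(sub["lineage"].to_numpy(), index=sub["cell_id"].to_numpy())
        res = it.interaction_test(g, types, n_perm=200, seed=0)
        finite = np.isfinite(res.p_interact)
        assert (res.p_interact[finite] >= 1 / 201).all()
        assert (res.p_avoid[finite] >= 1 / 201).all()

    def test_relabelling_cells_leaves_result_unchanged(self, rng):
        pts = rng.integers(0, 50, size=(20, 2))
        pts = np.unique(pts, axis=0)
        labels = rng.choice(["A", "B", "C"], size=len(pts)).tolist()
        seg1 = _seg_from_pixels([[tuple(p)] for p in pts], shape=(50, 50))
        # reverse cell ordering: ids permuted, same geometry and labels
        seg2_pixels = [[tuple(p)] for p in pts[::-1]]
        seg2 = _seg_from_pixels(seg2_pixels, shape=(50, 50))
        g1, g2 = it.build_adjacency(seg1, d=6), it.build_adjacency(seg2, d=6)
        s1 = pd.Series(labels, index=range(1, len(pts) + 1))
        s2 = pd.Series(labels[::-1], index=range(1, len(pts) + 1))
        r1 = it.interaction_test(g1, s1, n_perm=500, seed=7, type_order=("A", "B", "C"))
        r2 = it.interaction_test(g2, s2, n_perm=500, seed=7, type_order=("A", "B", "C"))
        np.testing.assert_allclose(r1.observed, r2.observed)

    def test_empty_type_reported_missing(self):
        seg = _seg_from_pixels([[(2, 2)], [(2, 6)], [(10, 10)]])
        g = it.build_adjacency(seg, d=6)
        labels = pd.Series(["A", "A", "B"], index=[1, 2, 3])
        res = it.interaction_test(
            g, labels, n_perm=100, seed=0, type_order=("A", "B", "C")
        )
        k = res.types.index("C")
        assert (res.call[k, :] == "missing").all()
        assert np.isnan(res.p_interact[k, :]).all()


class TestGroupHeatmap:
    def _result(self, core_id, call_ab):
        call = np.full((2, 2), "none", dtype=object)
        call[0, 1] = call_ab
        return it.InteractionResult(
            core_id, ("A", "B"), np.zeros((2, 2)), np.ones((2, 2)),
            np.ones((2, 2)), call, 100, 0.01,
        )

    def test_unanimous_interaction_is_one(self):
        results = [self._result(f"c{i}", "interaction") for i in range(4)]
        mats = it.group_heatmap(results, {f"c{i}": "solid" for i in range(4)})
        assert mats["solid"].loc["A", "B"] == 1.0

    def test_half_interaction_half_none(self):
        results = [self._result("c0", "interaction"), self._result("c1", "none")]
        mats = it.group_heatmap(results, {"c0": "g", "c1": "g"})
        assert mats["g"].loc["A", "B"] == 0.5

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="no cores"):
            it.group_heatmap([self._result("c0", "none")], {"c0": "g", "missing_core": "h"})

    def test_planted_attraction_confined_to_one_group(self, conditions8):
        """Attraction planted only in 'solid' cores raises that group's
        signed summary above the others."""
        panel, rules, props, targets = it.simple_conditions(8, proportions=[0.125] * 8)
        spec = it.SyntheticSpec(
            type_proportions=props, marker_targets=targets, cell_density=60.0,
            interactions=(
                it.InteractionEffect("B cell", "Tumour", 2.0, histologies=("solid",)),
            ),
        )
        results, groups = [], {}
        for i, hist in enumerate(["solid"] * 3 + ["lepidic"] * 3):
            core = it.generate_core(spec, seed=400 + i, core_id=f"c{i}", histology=hist)
            g = it.build_adjacency(core.seg, d=6)
            types = pd.Series(
                core.truth.df["lineage"].to_numpy(),
                index=core.truth.df["cell_id"].to_numpy(),
            )
            results.append(it.interaction_test(g, types, n_perm=500, seed=i))
            groups[f"c{i}"] = hist
        mats = it.group_heatmap(results, groups)
        a = results[0].types.index("B cell")
        b = results[0].types.index("Tumour")
        assert mats["solid"].iloc[a, b] > mats["lepidic"].iloc[a, b]
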