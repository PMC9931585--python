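"""Majority-vote phenotyping against per-pixel brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

import imctme as it
from imctme.masks import MarkerMask
from imctme.panel import MaskParams
from imctme.stacks import CellRegion


def _mask(arr):
    return MarkerMask("m", np.asarray(arr, dtype=bool), MaskParams())


@pytest.fixture()
def panel3():
    return it.MarkerPanel(
        [
            it.Marker("CD3", "lineage", 2),
            it.Marker("CD20", "lineage", 5),
            it.Marker("panCK", "lineage", 9),
        ]
    )


@pytest.fixture()
def rules3():
    return it.TypeRules({"CD3": "T cell", "CD20": "B cell", "panCK": "Tumour"})


class TestMajorityVector:
    def test_single_positive_marker(self, panel3):
        px = np.array([[0, 0], [0, 1], [0, 2], [1, 0], [1, 1]])
        cell = CellRegion(1, px, (0.4, 0.8))
        m_on = np.zeros((3, 3), bool)
        m_on[px[:, 0], px[:, 1]] = True
        masks = {"CD3": _mask(np.zeros((3, 3))), "CD20": _mask(m_on), "panCK": _mask(np.zeros((3, 3)))}
        mv = it.majority_vector(cell, masks, panel3.lineage_names)
        assert dict(zip(mv.markers, mv.counts)) == {"CD3": 0, "CD20": 5, "panCK": 0}

    def test_empty_masks_all_zero(self, panel3):
        cell = CellRegion(1, np.array([[0, 0]]), (0.0, 0.0))
        masks = {n: _mask(np.zeros((2, 2))) for n in panel3.lineage_names}
        assert it.majority_vector(cell, masks, panel3.lineage_names).counts.sum() == 0

    def test_missing_mask_named(self, panel3):
        cell = CellRegion(1, np.array([[0, 0]]), (0.0, 0.0))
        with pytest.raises(ValueError, match="CD20"):
            it.majority_vector(cell, {"CD3": _mask(np.zeros((2, 2)))}, panel3.lineage_names)

    def test_matches_per_pixel_tally(self, panel3, rng):
        shape = (10, 10)
        px = np.unique(rng.integers(0, 10, size=(20, 2)), axis=0)
        cell = CellRegion(1, px, tuple(px.mean(axis=0)))
        masks = {n: _mask(rng.random(shape) < 0.5) for n in panel3.lineage_names}
        mv = it.majority_vector(cell, masks, panel3.lineage_names)
        for k, name in enumerate(panel3.lineage_names):
            expected = sum(masks[name].mask[r, c] for r, c in px)
            assert mv.counts[k] == expected


class TestAssignLineage:
    def _mv(self, counts, markers=("CD3", "CD20", "panCK"), n=10):
        from imctme.phenotype import MajorityVector

        return MajorityVector(1, markers, np.array(counts), n)

    def test_clear_winner(self, panel3, rules3):
        assert it.assign_lineage(self._mv([0, 5, 0]), panel3, rules3) == "B cell"

    def test_tie_broken_by_priority(self, panel3, rules3):
        # CD3 rank 2 < CD20 rank 5 so CD3 wins the tie
        assert it.assign_lineage(self._mv([4, 4, 0]), panel3, rules3) == "T cell"

    def test_all_zero_is_undefined(self, panel3, rules3):
        assert it.assign_lineage(self._mv([0, 0, 0]), panel3, rules3) == "undefined"

    def test_unruled_winner_rejected(self, panel3):
        rules = it.TypeRules({"CD3": "T cell"})
        with pytest.raises(KeyError, match="CD20"):
            it.assign_lineage(self._mv([0, 5, 0]), panel3, rules)

    def test_combination_rule_secondary_majority(self):
        panel = it.MarkerPanel(
            [it.Marker("CD68", "lineage", 1), it.Marker("CD163", "lineage", 2)]
        )
        rules = it.TypeRules(
            {
                "CD68": it.CombinationRule("CD163", "Mac CD163+", "Mac CD163-", 0.5),
                "CD163": "Mac CD163+",
            }
        )
        from imctme.phenotype import MajorityVector

        pos = MajorityVector(1, ("CD68", "CD163"), np.array([8, 6]), 10)
        neg = MajorityVector(2, ("CD68", "CD163"), np.array([8, 2]), 10)
        assert it.assign_lineage(pos, panel, rules) == "Mac CD163+"
        assert it.assign_lineage(neg, panel, rules) == "Mac CD163-"

    def test_marker_order_permutation_invariant(self, panel3, rules3):
        from imctme.phenotype import MajorityVector

        a = MajorityVector(1, ("CD3", "CD20", "panCK"), np.array([3, 3, 1]), 5)
        b = MajorityVector(1, ("panCK", "CD20", "CD3"), np.array([1, 3, 3]), 5)
        assert it.assign_lineage(a, panel3, rules3) == it.assign_lineage(b, panel3, rules3)


class TestExpressionAndPositivity:
    def test_one_pixel_cell(self):
        stack = it.CoreImageStack("c", {"A": np.arange(9.0).reshape(3, 3)})
        cell = CellRegion(1, np.array([[1, 2]]), (1.0, 2.0))
        assert it.mean_expression(cell, stack)[0] == 5.0

    def test_constant_channel(self, rng):
        stack = it.CoreImageStack("c", {"A": np.full((6, 6), 3.5)})
        px = np.unique(rng.integers(0, 6, size=(8, 2)), axis=0)
        cell = CellRegion(1, px, tuple(px.mean(axis=0)))
        assert it.mean_expression(cell, stack)[0] == pytest.approx(3.5)

    def test_matches_brute_force_mean(self, rng):
        img = rng.random((12, 12)) * 20
        stack = it.CoreImageStack("c", {"A": img})
        px = np.unique(rng.integers(0, 12, size=(15, 2)), axis=0)
        cell = CellRegion(1, px, tuple(px.mean(axis=0)))
        expected = np.mean([img[r, c] for r, c in px])
        assert it.mean_expression(cell, stack)[0] == pytest.approx(expected)

    def test_positivity_extremes(self):
        px = np.array([[0, 0], [0, 1]])
        cell = CellRegion(1, px, (0.0, 0.5))
        assert it.functional_positivity(cell, _mask(np.ones((2, 2)))) is True
        assert it.functional_positivity(cell, _mask(np.zeros((2, 2)))) is False


class TestPercentileNormalize:
    def test_linear_range(self):
        vals = np.arange(101.0)
        out = it.percentile_normalize(vals, 95)
        assert out[95] == pytest.approx(1.0)
        assert out[100] == 1.0  # clipped
        assert out[19] == pytest.approx(19 / 95)

    def test_constant_positive_all_one(self):
        assert np.allclose(it.percentile_normalize(np.full(10, 4.0)), 1.0)

    def test_zero_percentile_warns(self):
        with pytest.warns(UserWarning, match="zero"):
            out = it.percentile_normalize(np.zeros(5))
        assert np.all(out == 0)

    def test_matches_interpolated_percentile(self, rng):
        vals = rng.random(50) * 9 + 1
        q = np.percentile(vals, 95)  # linear interpolation definition
        out = it.percentile_normalize(vals, 95)
        np.testing.assert_allclose(out, np.clip(vals / q, None, 1.0))


class TestFrequencies:
    def _table(self, lineages_list):
        df = pd.DataFrame(
            {
                "cell_id": range(1, len(lineages_list) + 1),
                "core_id": "c1",
                "centroid_row": 0.0,
                "centroid_col": 0.0,
                "lineage": lineages_list,
            }
        )
        return it.CellTable(df, lineages=("B cell", "Tumour", "NK", "undefined"))

    def test_fraction_of_total(self):
        table = self._table(["B cell"] * 4 + ["Tumour"] * 6)
        freq = it.compute_frequencies(table, types=("B cell", "Tumour"))
        assert freq.loc["c1", "freq_total_B cell"] == pytest.approx(0.4)
        assert freq.sum(axis=1).iloc[0] == pytest.approx(1.0)

    def test_empty_immune_denominator_is_missing(self):
        table = self._table(["Tumour"] * 5)
        freq = it.compute_frequencies(
            table, immune_types=("B cell", "NK"), types=("B cell", "NK", "Tumour")
        )
        assert np.isnan(freq.loc["c1", "freq_immune_B cell"])


class TestEndToEndPhenotyping:
    def test_noise_free_recovers_planted_labels(self, conditions8):
        panel, rules, props, targets = conditions8
        spec = it.SyntheticSpec(
            type_proportions=props, marker_targets=targets, cell_density=80.0,
            default_signal=it.MarkerSignal(sigma=0.0),
        )
        core = it.generate_core(spec, seed=3)
        with pytest.warns(UserWarning):  # two-valued channels collapse levels
            table = it.phenotype_core(core.stack, core.seg, panel, rules)
        acc = (table.df["lineage"].to_numpy() == core.truth.df["lineage"].to_numpy()).mean()
        assert acc >= 0.99

    def test_noisy_accuracy(self, conditions8, noisy_core, noisy_core_table):
        acc = (
            noisy_core_table.df["lineage"].to_numpy()
            == noisy_core.truth.df["lineage"].to_numpy()
        ).mean()
        assert acc >= 0.90

    def test_planted_functional_fraction_recovered(self, conditions8):
        panel, rules, props, targets = conditions8
        targets = dict(targets)
        targets["HIF1a"] = ()
        panel = it.MarkerPanel(panel.markers + [it.Marker("HIF1a", "functional")])
        spec = it.SyntheticSpec(
            type_proportions=props, marker_targets=targets, cell_density=80.0,
            functional_targets={"HIF1a": ("Neutrophil", 0.4)},
        )
        core = it.generate_core(spec, seed=21)
        table = it.phenotype_core(core.stack, core.seg, panel, rules)
        neut = table.df[core.truth.df["lineage"].to_numpy() == "Neutrophil"]
        planted = core.truth.df[core.truth.df["lineage"] == "Neutrophil"]["pos_HIF1a"]
        assert abs(neut["pos_HIF1a"].mean() - planted.mean()) <= 0.05
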