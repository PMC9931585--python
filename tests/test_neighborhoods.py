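"""Cellular neighbourhoods: window oracles, clustering recovery,
prevalence accounting."""

import numpy as np
import pandas as pd
import pytest

import imctme as it


def _table(positions, lineages, core_id="c1", lineage_set=("A", "B", "C", "undefined")):
    df = pd.DataFrame(
        {
            "cell_id": range(1, len(positions) + 1),
            "core_id": core_id,
            "centroid_row": [p[0] for p in positions],
            "centroid_col": [p[1] for p in positions],
            "lineage": lineages,
        }
    )
    return it.CellTable(df, lineages=lineage_set)


class TestWindowVectors:
    def test_pure_neighbourhood_vector(self):
        # a B-cell ring around the index cell: window is 1.0 at B
        positions = [(10, 10)] + [
            (10 + 3 * np.cos(a), 10 + 3 * np.sin(a))
            for a in np.linspace(0, 2 * np.pi, 10, endpoint=False)
        ]
        table = _table(positions, ["A"] + ["B"] * 10)
        w = it.window_vectors(table, n=10, types=("A", "B"))
        assert w.loc[("c1", 1), "B"] == 1.0
        assert w.loc[("c1", 1), "A"] == 0.0

    def test_window_larger_than_core_flagged(self):
        table = _table([(0, 0), (0, 5), (5, 0)], ["A", "B", "B"])
        w = it.window_vectors(table, n=10, types=("A", "B"))
        assert w["truncated"].all()
        assert w.loc[("c1", 1), "B"] == 1.0  # both other cells

    def test_tiny_core_skipped_with_warning(self):
        t1 = _table([(0, 0)], ["A"], core_id="solo")
        t2 = _table([(0, 0), (1, 1), (2, 2)], ["A", "B", "A"], core_id="ok")
        merged = it.CellTable(
            pd.concat([t1.df, t2.df], ignore_index=True), lineages=t1.lineages
        )
        with pytest.warns(UserWarning, match="solo"):
            w = it.window_vectors(merged, n=2, types=("A", "B"))
        assert set(w.index.get_level_values("core_id")) == {"ok"}

    def test_matches_brute_force_neighbours(self, rng):
        positions = rng.random((50, 2)) * 100
        lineages = rng.choice(["A", "B", "C"], size=50).tolist()
        table = _table(list(map(tuple, positions)), lineages)
        n = 7
        w = it.window_vectors(table, n=n, types=("A", "B", "C"))
        for i in range(50):
            d = np.hypot(*(positions - positions[i]).T)
            order = sorted(
                [j for j in range(50) if j != i], key=lambda j: (d[j], j)
            )[:n]
            counts = pd.Series([lineages[j] for j in order]).value_counts()
            for t in ("A", "B", "C"):
                assert w.loc[("c1", i + 1), t] == pytest.approx(counts.get(t, 0) / n)

    def test_window_rows_sum_to_one(self, noisy_core_table):
        w = it.window_vectors(noisy_core_table, n=10)
        types = [c for c in w.columns if c != "truncated"]
        np.testing.assert_allclose(w[types].sum(axis=1), 1.0)


class TestClusterWindows:
    def test_tcn_one_single_label(self, rng):
        positions = rng.random((30, 2)) * 50
        table = _table(list(map(tuple, positions)), ["A"] * 15 + ["B"] * 15)
        w = it.window_vectors(table, n=5, types=("A", "B"))
        model = it.cluster_windows(w, tCN=1, seed=0)
        assert set(model.labels) == {1}

    def test_tcn_exceeding_vectors_rejected(self, rng):
        table = _table([(0, 0), (1, 0), (2, 0)], ["A", "B", "A"])
        w = it.window_vectors(table, n=2, types=("A", "B"))
        with pytest.raises(ValueError, match="exceeds"):
            it.cluster_windows(w, tCN=10)

    def test_seed_deterministic(self, noisy_core_table):
        w = it.window_vectors(noisy_core_table, n=10)
        m1 = it.cluster_windows(w, tCN=4, seed=0)
        m2 = it.cluster_windows(w, tCN=4, seed=0)
        assert m1.labels.equals(m2.labels)

    def test_two_pure_planted_niches_recovered(self):
        """Two spatially separated pure blocks: CN labels match the
        blocks almost perfectly (ARI >= 0.99)."""
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(0)
        pos_a = rng.random((60, 2)) * 30
        pos_b = rng.random((60, 2)) * 30 + 200
        positions = np.vstack([pos_a, pos_b])
        lineages = ["A"] * 60 + ["B"] * 60
        table = _table(list(map(tuple, positions)), lineages)
        w = it.window_vectors(table, n=10, types=("A", "B"))
        model = it.cluster_windows(w, tCN=2, seed=0)
        truth = [0] * 60 + [1] * 60
        assert adjusted_rand_score(truth, model.labels.to_numpy()) >= 0.99


class TestPrevalence:
    def _model_from_labels(self, labels_by_core, tCN):
        idx = pd.MultiIndex.from_tuples(
            [
                (core, i + 1)
                for core, labels in labels_by_core.items()
                for i in range(len(labels))
            ],
            names=["core_id", "cell_id"],
        )
        values = [l for labels in labels_by_core.values() for l in labels]
        return it.NeighborhoodModel(
            n=10, tCN=tCN, types=("A",), centroids=np.zeros((tCN, 1)),
            labels=pd.Series(values, index=idx), batch_size=100, seed=0,
        )

    def test_single_cn_core(self):
        model = self._model_from_labels({"c1": [3] * 7}, tCN=3)
        prev = it.cn_prevalence(model)
        assert prev.loc["c1", "CN3"] == 100.0
        assert prev.loc["c1", "CN1"] == 0.0

    def test_even_split(self):
        model = self._model_from_labels({"c1": [1] * 5 + [2] * 5}, tCN=2)
        prev = it.cn_prevalence(model)
        assert prev.loc["c1", "CN1"] == prev.loc["c1", "CN2"] == 50.0

    def test_matches_brute_force_tally_and_sums_100(self, rng):
        labels = {f"c{k}": rng.integers(1, 5, size=37).tolist() for k in range(4)}
        model = self._model_from_labels(labels, tCN=4)
        prev = it.cn_prevalence(model)
        for core, ls in labels.items():
            for cn in range(1, 5):
                assert prev.loc[core, f"CN{cn}"] == pytest.approx(
                    100 * ls.count(cn) / len(ls)
                )
        rounded = it.cn_prevalence(model, decimals=0)
        assert (rounded.sum(axis=1) == 100.0).all()  # exact at integer precision
        rounded2 = it.cn_prevalence(model, decimals=2)
        np.testing.assert_allclose(rounded2.sum(axis=1), 100.0, rtol=0, atol=1e-9)


class TestCharacterize:
    def test_pure_cn_maximal_in_own_type(self, rng):
        pos_a = rng.random((40, 2)) * 20
        pos_b = rng.random((40, 2)) * 20 + 150
        table = _table(
            list(map(tuple, np.vstack([pos_a, pos_b]))), ["A"] * 40 + ["B"] * 40
        )
        w = it.window_vectors(table, n=8, types=("A", "B"))
        model = it.cluster_windows(w, tCN=2, seed=0)
        prof = it.characterize_cns(model, w)
        # the A-dominated CN has the top z-score in column A
        cn_a = model.labels.iloc[0]
        assert prof.loc[f"CN{cn_a}", "A"] == prof["A"].max()


class TestSweep:
    def test_single_pair_matches_direct_run(self, noisy_core_table):
        clin = pd.DataFrame(
            {
                "survival_time": [12.0],
                "event": [True],
            },
            index=pd.Index(["p1"], name="patient_id"),
        )
        mapping = {noisy_core_table.core_ids[0]: "p1"}
        # single-core cohort: survival scan degenerates, but the CN fit
        # itself must match a direct model fit
        w = it.window_vectors(noisy_core_table, n=8)
        direct = it.cluster_windows(w, tCN=3, seed=0, n=8)
        res = it.sweep(
            noisy_core_table, clin, mapping, n_values=(8,), tCN_values=(3,), seed=0
        )
        assert set(res["cn"]) == {f"CN{i}" for i in range(1, 4)}
        prev_direct = it.cn_prevalence(direct)
        assert prev_direct.shape == (1, 3)


def test_sweep_flags_planted_survival_niche_across_window_sizes():
    """A survival-linked niche stays significant across window sizes:
    for each n in {5, 10, 20} (tCN=4), at least one CN's z-stratified
    log-rank p-value falls below 0.05."""
    panel, rules, props, targets = it.simple_conditions(6)
    spec = it.SyntheticSpec(
        type_proportions=props, marker_targets=targets,
        n_patients=40, cell_density=30.0, image_size=(160, 160),
        niches=(it.NicheSpec("lymphoid", ("Mast cell", "DC"), weight=0.95, radius=22.0),),
        outcome_model=it.OutcomeSpec(hazard_coefs={"niche:lymphoid": -1.0}, censoring_rate=0.2),
    )
    cohort = it.generate_cohort(spec, seed=9)
    merged = it.CellTable(
        pd.concat([c.truth.df for c in cohort.cores], ignore_index=True),
        lineages=cohort.cores[0].truth.lineages,
        channels=cohort.cores[0].truth.channels,
    )
    clin = cohort.clinical.df.set_index("patient_id")
    res = it.sweep(
        merged, clin, cohort.clinical.core_to_patient,
        n_values=(5, 10, 20), tCN_values=(4,), seed=0,
    )
    for _, grp in res.groupby("n"):
        assert grp["p_value"].min() < 0.05
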