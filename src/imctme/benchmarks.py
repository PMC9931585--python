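"""Reference experiments exercising each analysis stage end-to-end on
synthetic cohorts at fixed study conditions.

Every function regenerates its inputs from a seed, runs the analysis
through the public API and returns plain-number metrics.  They back
both the acceptance checks and the reproduction script, so the numbers
reported there are always recomputed, never stored.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import synthetic
from .interactions import build_adjacency, interaction_test
from .neighborhoods import cluster_windows, cn_prevalence, window_vectors
from .phenotype import phenotype_core
from .predict import (
    baseline_score,
    channel_embeddings,
    features_from_subset,
    train_eval,
)
from .survival import kaplan_meier, logrank, survival_association
from .synthetic import (
    InteractionEffect,
    MarkerSignal,
    NicheSpec,
    OutcomeSpec,
    SyntheticSpec,
    generate_core,
    generate_spatial_signal_cohort,
    sample_outcomes,
    simple_conditions,
)


def _sub_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


# ---------------------------------------------------------------------------
# Phenotyping fidelity


def phenotyping_fidelity(seed: int = 0, cell_density: float = 80.0) -> dict:
    """Majority-vote lineage accuracy against planted labels on one
    noise-free and one spec-noise core (~520 cells, 8 types)."""
    import warnings

    panel, rules, props, targets = simple_conditions(8)
    s_clean, s_noisy = _sub_seeds(seed, 2)
    out = {}
    for label, sig, s in (
        ("clean", MarkerSignal(sigma=0.0), s_clean),
        ("noisy", MarkerSignal(), s_noisy),
    ):
        spec = SyntheticSpec(
            type_proportions=props, marker_targets=targets,
            cell_density=cell_density, default_signal=sig,
        )
        core = generate_core(spec, seed=s)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = phenotype_core(core.stack, core.seg, panel, rules)
        acc = float(
            (table.df["lineage"].to_numpy() == core.truth.df["lineage"].to_numpy()).mean()
        )
        out[f"accuracy_{label}"] = acc
        out[f"n_cells_{label}"] = len(table)
    return out


# ---------------------------------------------------------------------------
# Mask-step oracle equivalence


def _median_oracle(img: np.ndarray, window: int) -> np.ndarray:
    from numpy.lib.stride_tricks import sliding_window_view

    r = window // 2
    pad = np.pad(img, r, mode="edge")
    win = sliding_window_view(pad, (window, window))
    return np.median(win.reshape(img.shape[0], img.shape[1], -1), axis=2)


def _enum_partition_oracle(values: np.ndarray, k: int) -> tuple[np.ndarray, float]:
    """Exhaustive 1-D k-means: optimal clusters are contiguous in sorted
    order, so every placement of the k-1 boundaries between the distinct
    values is enumerated and the weighted-SSE minimum returned.

    Returns (level raster with values 1..k ordered by intensity, SSE).
    """
    from itertools import combinations

    vals, counts = np.unique(values, return_counts=True)
    u = len(vals)
    cw = np.concatenate([[0.0], np.cumsum(counts)])
    cwx = np.concatenate([[0.0], np.cumsum(counts * vals)])
    cwx2 = np.concatenate([[0.0], np.cumsum(counts * vals * vals)])

    def seg(i, j):  # SSE of vals[i..j] inclusive
        w = cw[j + 1] - cw[i]
        s = cwx[j + 1] - cwx[i]
        return cwx2[j + 1] - cwx2[i] - s * s / w

    best_sse, best_cuts = np.inf, None
    for cuts in combinations(range(1, u), k - 1):
        bounds = (0,) + cuts + (u,)
        sse = sum(seg(bounds[c], bounds[c + 1] - 1) for c in range(k))
        if sse < best_sse - 1e-12:
            best_sse, best_cuts = sse, cuts
    thresholds = vals[list(best_cuts)]
    levels = np.searchsorted(thresholds, values.ravel(), side="right") + 1
    return levels.reshape(values.shape), float(best_sse)


def _components_oracle(mask: np.ndarray) -> np.ndarray:
    """8-connected labelling by BFS."""
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
            for da in (-1, 0, 1):
                for db in (-1, 0, 1):
                    x, y = a + da, b + db
                    if (
                        0 <= x < mask.shape[0] and 0 <= y < mask.shape[1]
                        and mask[x, y] and not comp[x, y]
                    ):
                        comp[x, y] = cur
                        stack.append((x, y))
    return comp


def mask_oracle_equivalence(seed: int = 0, n_rasters: int = 100) -> dict:
    """Exact agreement of median filter, intensity quantization and blob
    removal with brute-force oracles on random integer rasters."""
    from .masks import median_smooth, quantize_levels, remove_small_blobs

    rng = np.random.default_rng(seed)
    agree = {"median": 0, "quantize": 0, "blobs": 0}
    for i in range(n_rasters):
        h, w = rng.integers(16, 65, size=2)
        img = rng.integers(0, 30, size=(h, w)).astype(float)
        if np.array_equal(median_smooth(img, 3), _median_oracle(img, 3)):
            agree["median"] += 1
        k = 4
        lv = quantize_levels(img, k)
        oracle_lv, oracle_sse = _enum_partition_oracle(img, k)
        if np.array_equal(lv, oracle_lv):
            agree["quantize"] += 1
        mask = rng.random((h, w)) < 0.35
        comp = _components_oracle(mask)
        sizes = np.bincount(comp.ravel())
        expected = np.isin(comp, np.flatnonzero(sizes >= 4)) & (comp > 0)
        if np.array_equal(remove_small_blobs(mask, 4), expected):
            agree["blobs"] += 1
    return {f"{k}_exact_fraction": v / n_rasters for k, v in agree.items()} | {
        "n_rasters": n_rasters
    }


# ---------------------------------------------------------------------------
# Interaction testing


def interaction_calibration(
    seed: int = 0, n_cores: int = 30, n_perm: int = 1000, alpha: float = 0.01,
    d: float = 14.0,
) -> dict:
    """Type-I error of the permutation test under random labelling.

    Each one-sided test (core x ordered pair x side) is calibrated at
    alpha; the flagged fraction estimates the size of the test.  Cores
    hold 100 cells of 5 equally frequent types.  The adjacency radius
    is set so the graph is well connected (mean degree ~5): on sparse
    graphs the discrete statistic makes the permutation test strictly
    conservative (type-I error below alpha), which would mask the
    calibration being measured here.
    """
    panel, rules, props, targets = simple_conditions(5, proportions=[0.2] * 5)
    spec = SyntheticSpec(
        type_proportions=props, marker_targets=targets,
        cell_density=61.04, image_size=(128, 128),
    )
    flagged = total = 0
    for s in _sub_seeds(seed, n_cores):
        core = generate_core(spec, seed=s)
        graph = build_adjacency(core.seg, d=d)
        df = core.truth.df
        types = pd.Series(df["lineage"].to_numpy(), index=df["cell_id"].to_numpy())
        res = interaction_test(graph, types, n_perm=n_perm, alpha=alpha, seed=s)
        for p in (res.p_interact, res.p_avoid):
            finite = np.isfinite(p)
            flagged += int((p[finite] < alpha).sum())
            total += int(finite.sum())
    frac = flagged / total
    return {
        "flagged_fraction": frac,
        "alpha": alpha,
        "n_tests": total,
        "mc_se": float(np.sqrt(alpha * (1 - alpha) / total)),
    }


def planted_interaction_recovery(
    seed: int = 0, n_cores: int = 50, strength: float = 2.0, n_perm: int = 1000
) -> dict:
    """Sign-correct call rate for planted attraction (half the cores)
    and repulsion (other half) between two types at density 60."""
    panel, rules, props, targets = simple_conditions(8, proportions=[0.125] * 8)
    correct = 0
    seeds = _sub_seeds(seed, n_cores)
    for i, s in enumerate(seeds):
        sgn = 1.0 if i % 2 == 0 else -1.0
        spec = SyntheticSpec(
            type_proportions=props, marker_targets=targets, cell_density=60.0,
            interactions=(InteractionEffect("B cell", "Tumour", sgn * strength),),
        )
        core = generate_core(spec, seed=s)
        graph = build_adjacency(core.seg, d=6)
        df = core.truth.df
        types = pd.Series(df["lineage"].to_numpy(), index=df["cell_id"].to_numpy())
        res = interaction_test(graph, types, n_perm=n_perm, seed=s)
        a = res.types.index("B cell")
        b = res.types.index("Tumour")
        want = "interaction" if sgn > 0 else "avoidance"
        correct += res.call[a, b] == want
    return {"recovery_rate": correct / n_cores, "n_cores": n_cores}


# ---------------------------------------------------------------------------
# Cellular neighbourhoods


def cn_recovery(seed: int = 0, n_cores: int = 4) -> dict:
    """ARI of CN labels against three planted niches at spec noise,
    with n = 10 and tCN = the planted niche count."""
    panel, rules, props, targets = simple_conditions(8)
    spec = SyntheticSpec(
        type_proportions=props, marker_targets=targets, cell_density=40.0,
        image_size=(320, 320),
        niches=(
            NicheSpec("lymphoid", ("B cell", "NK", "Neutrophil"), 0.95, 25.0),
            NicheSpec("tumour", ("Tumour", "Fibroblast"), 0.95, 25.0),
            NicheSpec("vascular", ("Endothelial", "DC", "Mast cell"), 0.95, 25.0),
        ),
    )
    tables, planted = [], []
    for s in _sub_seeds(seed, n_cores):
        core = generate_core(spec, seed=s, core_id=f"core{s}")
        tables.append(phenotype_core(core.stack, core.seg, panel, rules))
        planted.append(core.niche)
    merged = tables[0].__class__(
        pd.concat([t.df for t in tables], ignore_index=True),
        lineages=tables[0].lineages, channels=tables[0].channels,
    )
    windows = window_vectors(merged, n=10)
    model = cluster_windows(windows, tCN=3, seed=0, n=10)
    truth = pd.concat(planted, keys=[t.core_ids[0] for t in tables],
                      names=["core_id", "cell_id"])
    truth = truth[truth != ""]
    pred = model.labels.loc[truth.index]
    prev = cn_prevalence(model, decimals=0)
    return {
        "ari": float(adjusted_rand_score(truth, pred)),
        "n_cells": len(model.labels),
        "prevalence_sums_exact": bool((prev.sum(axis=1) == 100.0).all()),
    }


# ---------------------------------------------------------------------------
# Survival


def survival_closed_forms() -> dict:
    km = kaplan_meier([1, 2, 3], [True, True, True])
    res = logrank([1, 2, 4], [1, 1, 1], [3, 5, 6], [1, 1, 0])
    return {
        "km_s1": float(km.survival[0]),
        "km_s2": float(km.survival[1]),
        "km_s3": float(km.survival[2]),
        "logrank6_chi_square": res.chi_square,
        "logrank6_expected_a": float(res.expected[0]),
    }


def survival_power(
    seed: int = 0, n_replicates: int = 200, n_patients: int = 200,
    hazard_ratio: float = 2.0, censoring: float = 0.2,
) -> dict:
    """Power of the z-stratified log-rank test at a planted hazard
    ratio between the high and low strata."""
    hits = 0
    for s in _sub_seeds(seed, n_replicates):
        rng = np.random.default_rng(s)
        v = pd.Series(rng.standard_normal(n_patients))
        lam = np.where(v >= v.mean(), hazard_ratio, 1.0)
        t = rng.exponential(60.0, n_patients) / lam
        c = rng.exponential(60.0 * (1 - censoring) / censoring, n_patients)
        sa = survival_association(
            v, pd.Series(np.minimum(t, c)), pd.Series(t <= c)
        )
        hits += sa.logrank.p_value < 0.05
    return {"power": hits / n_replicates, "n_replicates": n_replicates}


def survival_null_uniformity(
    seed: int = 0, n_replicates: int = 500, n_patients: int = 100
) -> dict:
    """Kolmogorov-Smirnov check that log-rank p-values are uniform when
    the stratifying value is independent of survival."""
    from scipy import stats

    pvals = []
    for s in _sub_seeds(seed, n_replicates):
        rng = np.random.default_rng(s)
        v = pd.Series(rng.standard_normal(n_patients))
        t = rng.exponential(60.0, n_patients)
        c = rng.exponential(240.0, n_patients)
        sa = survival_association(v, pd.Series(np.minimum(t, c)), pd.Series(t <= c))
        pvals.append(sa.logrank.p_value)
    ks = stats.kstest(pvals, "uniform")
    return {"ks_p": float(ks.pvalue), "n_replicates": n_replicates}


# ---------------------------------------------------------------------------
# Outcome prediction


def prediction_comparison(seed: int = 0, n_cores: int = 120, n_positive: int = 30) -> dict:
    """Raw-channel vs cell-frequency vs clinical feature sources on a
    cohort whose outcome differs only in spatial arrangement."""
    cohort = generate_spatial_signal_cohort(n_cores=n_cores, n_positive=n_positive, seed=seed)
    y = cohort.labels
    emb = channel_embeddings(cohort.stacks, "testhash")
    X_raw = features_from_subset(emb, list(emb))
    rep_raw = train_eval(X_raw, y, groups=cohort.patients, seed=seed, source="raw")

    types = sorted(cohort.truths[0].df["lineage"].unique())
    X_freq = np.array(
        [
            [t.df["lineage"].value_counts(normalize=True).get(tt, 0.0) for tt in types]
            for t in cohort.truths
        ]
    )
    rep_freq = train_eval(
        X_freq, y, groups=cohort.patients, seed=seed,
        n_components=min(9, len(types)), source="freq",
    )
    cov = cohort.covariates.loc[cohort.patients]
    X_clin = pd.get_dummies(
        cov[["sex", "age", "bmi", "smoking", "pack_years", "stage", "histology"]],
        columns=["sex", "smoking", "stage", "histology"],
    ).to_numpy(dtype=float)
    rep_clin = train_eval(X_clin, y, groups=cohort.patients, seed=seed, source="clinical")
    base = baseline_score(y)
    return {
        "accuracy_raw": rep_raw.mean_accuracy,
        "accuracy_freq": rep_freq.mean_accuracy,
        "accuracy_clinical": rep_clin.mean_accuracy,
        "baseline": base,
        "raw_minus_freq": rep_raw.mean_accuracy - rep_freq.mean_accuracy,
        "n_cores": n_cores,
    }


# ---------------------------------------------------------------------------
# Pipeline determinism


def pipeline_determinism(seed: int = 0, out_root=None) -> dict:
    """Byte-identity of cell tables, CN labels and prediction reports
    across two runs of the same config + seed."""
    import tempfile
    from pathlib import Path

    from .pipeline import run_pipeline

    cfg = {
        "conditions": {"kind": "simple", "n_types": 6},
        "synthetic": {
            "n_patients": 6, "cell_density": 20.0, "image_size": [128, 128],
            "outcome_model": {"logistic_intercept": 0.0},
        },
        "interactions": {"n_perm": 100},
        "neighborhoods": {"n": 8, "tcn": 3},
        "predict": {"sources": ["freq"], "folds": 2, "n_components": 3},
        "stages": ["synth", "masks", "phenotype", "interactions", "neighborhoods", "predict"],
    }
    with tempfile.TemporaryDirectory(dir=out_root) as tmp:
        tmp = Path(tmp)
        run_pipeline(cfg, tmp / "a", seed=seed)
        run_pipeline(cfg, tmp / "b", seed=seed)
        files = ["cells.csv", "cn_labels.csv", "predictions.json", "interactions.csv"]
        identical = all(
            (tmp / "a" / f).read_bytes() == (tmp / "b" / f).read_bytes() for f in files
        )
    return {"byte_identical": bool(identical), "n_files_compared": len(files)}
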