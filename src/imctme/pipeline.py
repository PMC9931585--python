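"""Declarative pipeline: chained stages over on-disk artifacts.

A single JSON config names the study conditions (panel + type rules +
synthetic-cohort spec, or directories of real per-core TIFFs), the
stages to run and their parameters.  Stages exchange data through files
in the output directory, so any stage can run in a later invocation as
long as its prerequisites exist on disk.  Every run writes a
machine-readable run log with the full configuration and all seeds; a
fixed config + seed reproduces every output byte for byte.

Stage order and prerequisites::

    synth -> masks -> phenotype -> interactions
                               \\-> neighborhoods -> survival
    synth -> predict (uses stacks + phenotype frequencies + clinical)
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import synthetic
from .interactions import build_adjacency, group_heatmap, interaction_test
from .masks import build_marker_mask
from .neighborhoods import cluster_windows, cn_prevalence, cn_survival_scan, window_vectors
from .panel import MarkerPanel, luad_panel
from .phenotype import TypeRules, compute_frequencies, luad_type_rules, phenotype_core
from .predict import baseline_score, channel_embeddings, features_from_subset, train_eval
from .stacks import read_core_stack, read_segmentation, write_core_stack, write_mask, write_segmentation
from .tables import read_cell_table, read_clinical_table, write_cell_table, write_clinical_table

STAGES = ("synth", "masks", "phenotype", "interactions", "neighborhoods", "survival", "predict")

_PREREQ = {
    "synth": [],
    "masks": ["stacks"],
    "phenotype": ["stacks", "segs"],
    "interactions": ["segs", "cells"],
    "neighborhoods": ["cells"],
    "survival": ["cn_prevalence", "clinical"],
    "predict": ["stacks", "cells", "clinical"],
}

_PRODUCES = {
    "synth": ["stacks", "segs", "cells_truth", "clinical", "features"],
    "masks": ["masks"],
    "phenotype": ["cells", "frequencies"],
    "interactions": ["interactions"],
    "neighborhoods": ["cn_labels", "cn_prevalence", "cn_profiles"],
    "survival": ["survival_scan"],
    "predict": ["predictions"],
}

_ARTIFACT_PATH = {
    "stacks": "stacks",
    "segs": "segs",
    "masks": "masks",
    "cells_truth": "cells_truth.csv",
    "cells": "cells.csv",
    "frequencies": "frequencies.csv",
    "clinical": "clinical.csv",
    "features": "features_truth.csv",
    "interactions": "interactions.csv",
    "cn_labels": "cn_labels.csv",
    "cn_prevalence": "cn_prevalence.csv",
    "cn_profiles": "cn_profiles.csv",
    "survival_scan": "survival_scan.csv",
    "predictions": "predictions.json",
}


def load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        config = json.loads(Path(config).read_text())
    return dict(config)


def resolve_conditions(config: dict):
    """Panel, type rules and synthetic marker model from the config."""
    cond = config.get("conditions", {"kind": "simple", "n_types": 8})
    if cond.get("kind") == "luad":
        panel = luad_panel()
        rules = luad_type_rules()
        props = synthetic.luad_type_proportions()
        targets = synthetic.luad_marker_targets()
    else:
        panel, rules, props, targets = synthetic.simple_conditions(
            cond.get("n_types", 8), cond.get("proportions")
        )
    for name, params in config.get("mask_params", {}).items():
        panel = panel.with_mask_params(name, **params)
    return panel, rules, props, targets


def _artifact(out_dir: Path, name: str) -> Path:
    return out_dir / _ARTIFACT_PATH[name]


def run_pipeline(config, out_dir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Execute the requested stages in dependency order.

    Raises before doing any work if a stage's prerequisites are neither
    on disk nor produced by an earlier requested stage.
    """
    config = load_config(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stages = config.get("stages", list(STAGES))
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ValueError(f"unknown stages: {unknown}")
    stages = [s for s in STAGES if s in stages]

    produced: set[str] = set()
    for stage in stages:
        for req in _PREREQ[stage]:
            if req in produced or _artifact(out_dir, req).exists():
                continue
            raise ValueError(
                f"stage {stage!r} requires {req!r}, which is neither on disk "
                f"nor produced by an earlier requested stage"
            )
        produced.update(_PRODUCES[stage])

    panel, rules, props, targets = resolve_conditions(config)
    artifacts: dict[str, Path] = {}
    for stage in stages:
        runner = globals()[f"_stage_{stage}"]
        artifacts.update(runner(config, out_dir, seed, panel, rules, props, targets))

    log = {
        "config": config,
        "seed": seed,
        "stages_run": stages,
        "artifacts": {k: str(v) for k, v in sorted(artifacts.items())},
    }
    (out_dir / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True))
    return artifacts


def _list_cores(out_dir: Path) -> list[str]:
    return sorted(p.stem for p in (out_dir / "stacks").glob("*.tif"))


def _stage_synth(config, out_dir, seed, panel, rules, props, targets):
    params = dict(config.get("synthetic", {}))
    params.setdefault("type_proportions", props)
    params.setdefault("marker_targets", targets)
    if "niches" in params:
        params["niches"] = tuple(synthetic.NicheSpec(**n) for n in params["niches"])
    if "interactions" in params:
        params["interactions"] = tuple(
            synthetic.InteractionEffect(**e) for e in params["interactions"]
        )
    if "outcome_model" in params:
        params["outcome_model"] = synthetic.OutcomeSpec(**params["outcome_model"])
    if "image_size" in params:
        params["image_size"] = tuple(params["image_size"])
    spec = synthetic.SyntheticSpec(**params)
    cohort = synthetic.generate_cohort(spec, seed=seed)
    for core in cohort.cores:
        write_core_stack(core.stack, out_dir / "stacks" / f"{core.stack.core_id}.tif")
        write_segmentation(core.seg, out_dir / "segs" / f"{core.seg.core_id}.tif")
    truth = pd.concat([c.truth.df for c in cohort.cores], ignore_index=True)
    truth_path = out_dir / "cells_truth.csv"
    truth.to_csv(truth_path, index=False, lineterminator="\n")
    write_clinical_table(cohort.clinical, out_dir / "clinical.csv")
    cohort.features.round(8).to_csv(out_dir / "features_truth.csv", lineterminator="\n")
    return {
        "stacks": out_dir / "stacks",
        "segs": out_dir / "segs",
        "cells_truth": truth_path,
        "clinical": out_dir / "clinical.csv",
        "features": out_dir / "features_truth.csv",
    }


def _stage_masks(config, out_dir, seed, panel, rules, props, targets):
    sub_panel = panel.subset(list(targets))
    for core_id in _list_cores(out_dir):
        stack = read_core_stack(out_dir / "stacks" / f"{core_id}.tif", sub_panel, core_id=core_id)
        for name in stack.channel_names:
            mm = build_marker_mask(stack[name], panel[name].mask_params, marker=name, seed=seed)
            write_mask(mm.mask, out_dir / "masks" / core_id / f"{name}.tif")
    return {"masks": out_dir / "masks"}


def _stage_phenotype(config, out_dir, seed, panel, rules, props, targets):
    tables = []
    sub_panel = panel.subset(list(targets))
    for core_id in _list_cores(out_dir):
        stack = read_core_stack(out_dir / "stacks" / f"{core_id}.tif", sub_panel, core_id=core_id)
        seg = read_segmentation(out_dir / "segs" / f"{core_id}.tif", core_id=core_id)
        tables.append(phenotype_core(stack, seg, sub_panel, rules, seed=seed))
    merged = tables[0].__class__(
        pd.concat([t.df for t in tables], ignore_index=True),
        lineages=tables[0].lineages,
        channels=tables[0].channels,
        functional=tables[0].functional,
    )
    write_cell_table(merged, out_dir / "cells.csv")
    freq = compute_frequencies(merged)
    freq.round(8).to_csv(out_dir / "frequencies.csv", lineterminator="\n")
    return {"cells": out_dir / "cells.csv", "frequencies": out_dir / "frequencies.csv"}


def _read_cells(out_dir, rules, targets):
    return read_cell_table(
        out_dir / "cells.csv",
        lineages=rules.labels,
        channels=tuple(targets),
    )


def _stage_interactions(config, out_dir, seed, panel, rules, props, targets):
    params = config.get("interactions", {})
    d = params.get("d", 6.0)
    rule = params.get("rule", "boundary")
    n_perm = params.get("n_perm", 1000)
    alpha = params.get("alpha", 0.01)
    cells = _read_cells(out_dir, rules, targets)
    type_order = tuple(sorted(set(cells.df["lineage"])))
    results = []
    for i, core_id in enumerate(cells.core_ids):
        seg = read_segmentation(out_dir / "segs" / f"{core_id}.tif", core_id=core_id)
        graph = build_adjacency(seg, d=d, rule=rule)
        sub = cells.for_core(core_id)
        types = pd.Series(sub["lineage"].to_numpy(), index=sub["cell_id"].to_numpy())
        results.append(
            interaction_test(
                graph, types, n_perm=n_perm, alpha=alpha, seed=seed + i,
                type_order=type_order,
            )
        )
    long = pd.concat([r.to_frame() for r in results], ignore_index=True)
    long.round(8).to_csv(out_dir / "interactions.csv", index=False, lineterminator="\n")
    if (out_dir / "clinical.csv").exists():
        clin = read_clinical_table(out_dir / "clinical.csv")
        hist = dict(zip(clin.df["patient_id"], clin.df["histology"]))
        groups = {cid: hist[pid] for cid, pid in clin.core_to_patient.items()}
        groups = {cid: g for cid, g in groups.items() if cid in set(cells.core_ids)}
        mats = group_heatmap(results, groups)
        for g, mat in mats.items():
            mat.round(8).to_csv(out_dir / f"interactions_{g}.csv", lineterminator="\n")
    return {"interactions": out_dir / "interactions.csv"}


def _stage_neighborhoods(config, out_dir, seed, panel, rules, props, targets):
    params = config.get("neighborhoods", {})
    n = params.get("n", 10)
    tcn = params.get("tcn", 10)
    batch = params.get("batch_size", 1024)
    cells = _read_cells(out_dir, rules, targets)
    windows = window_vectors(cells, n=n)
    model = cluster_windows(windows, tCN=tcn, batch_size=batch, seed=seed, n=n)
    model.labels.to_frame().to_csv(out_dir / "cn_labels.csv", lineterminator="\n")
    prev = cn_prevalence(model)
    prev.round(8).to_csv(out_dir / "cn_prevalence.csv", lineterminator="\n")
    from .neighborhoods import characterize_cns

    characterize_cns(model, windows).round(8).to_csv(
        out_dir / "cn_profiles.csv", lineterminator="\n"
    )
    return {
        "cn_labels": out_dir / "cn_labels.csv",
        "cn_prevalence": out_dir / "cn_prevalence.csv",
        "cn_profiles": out_dir / "cn_profiles.csv",
    }


def _stage_survival(config, out_dir, seed, panel, rules, props, targets):
    prev = pd.read_csv(out_dir / "cn_prevalence.csv", index_col=0)
    clin = read_clinical_table(out_dir / "clinical.csv")
    clin_idx = clin.df.set_index("patient_id")
    scan = cn_survival_scan(prev, clin_idx, clin.core_to_patient)
    scan.round(8).to_csv(out_dir / "survival_scan.csv", lineterminator="\n")
    return {"survival_scan": out_dir / "survival_scan.csv"}


def _stage_predict(config, out_dir, seed, panel, rules, props, targets):
    params = config.get("predict", {})
    target = params.get("target", "progression")
    sources = params.get("sources", ["freq", "raw"])
    backbone = params.get("backbone", "testhash")
    k = params.get("folds", 5)
    ncomp = params.get("n_components", 9)
    channels = params.get("channels")

    clin = read_clinical_table(out_dir / "clinical.csv")
    core_to_patient = clin.core_to_patient
    clin_idx = clin.df.set_index("patient_id")
    sub_panel = panel.subset(list(targets))
    core_ids = _list_cores(out_dir)
    patients = np.array([core_to_patient[c] for c in core_ids])
    raw = clin_idx.loc[patients, target]
    if target == "survival3y":
        y = np.where(raw.to_numpy() >= 36.0, ">=3y", "<3y")
    else:
        y = raw.astype(str).to_numpy()

    reports = {}
    for source in sources:
        if source == "freq":
            freq = pd.read_csv(out_dir / "frequencies.csv", index_col=0)
            X = freq.loc[core_ids].to_numpy(dtype=float)
        elif source == "clinical":
            cov = clin_idx.loc[patients, ["sex", "age", "bmi", "smoking", "pack_years", "stage", "histology"]]
            X = pd.get_dummies(cov, columns=["sex", "smoking", "stage", "histology"]).to_numpy(dtype=float)
        elif source == "raw":
            stacks = [
                read_core_stack(out_dir / "stacks" / f"{c}.tif", sub_panel, core_id=c)
                for c in core_ids
            ]
            emb = channel_embeddings(stacks, backbone, channels)
            X = features_from_subset(emb, list(emb))
        else:
            raise ValueError(f"unknown feature source {source!r}")
        rep = train_eval(
            X, y, groups=patients, k=k, seed=seed, n_components=ncomp,
            target=target, source=source,
        )
        reports[source] = rep.to_dict()
    reports["baseline"] = round(baseline_score(y), 6)
    path = out_dir / "predictions.json"
    path.write_text(json.dumps(reports, indent=2, sort_keys=True))
    return {"predictions": path}
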