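"""Cellular neighbourhood (CN) discovery.

Each cell is summarized by its *window*: the cell-type frequency vector
of its n nearest spatial neighbours (Euclidean distance on centroids,
within the same core only; ties broken by cell id; the index cell is
excluded by default, with an ``include_self`` switch since both
conventions are in use).  Windows from all cores are pooled and
clustered with mini-batch k-means into tCN cohort-level neighbourhoods;
each cell inherits the CN of its defining window.  Per-core CN
prevalence is expressed in percent and sums to 100.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import MiniBatchKMeans

from .phenotype import percentile_normalize, zscore
from .survival import logrank, zscore_stratify
from .tables import CellTable


def window_vectors(
    table: CellTable,
    n: int = 10,
    types: tuple[str, ...] | None = None,
    include_self: bool = False,
) -> pd.DataFrame:
    """Type-frequency window of the n nearest neighbours of every cell.

    Returns a frame indexed by (core_id, cell_id) with one column per
    type plus a boolean ``truncated`` flag for cells whose core holds
    fewer than n neighbours (their window uses all available cells).
    Cores with fewer than 2 cells are skipped with a warning.
    """
    if types is None:
        types = table.lineages
    tindex = {t: i for i, t in enumerate(types)}
    frames = []
    for core_id in table.core_ids:
        sub = table.for_core(core_id).sort_values("cell_id")
        m = len(sub)
        if m < 2:
            warnings.warn(f"core {core_id!r} has < 2 cells; skipped", stacklevel=2)
            continue
        pts = sub[["centroid_row", "centroid_col"]].to_numpy(dtype=float)
        y = np.array([tindex[v] for v in sub["lineage"]])
        d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
        if not include_self:
            np.fill_diagonal(d2, np.inf)
        # columns are in ascending cell id order, so a stable sort
        # breaks distance ties by cell id
        order = np.argsort(d2, axis=1, kind="stable")
        avail = m if include_self else m - 1
        k = min(n, avail)
        neigh = order[:, :k]
        freq = np.zeros((m, len(types)))
        np.add.at(freq, (np.repeat(np.arange(m), k), y[neigh].ravel()), 1.0)
        freq /= k
        df = pd.DataFrame(freq, columns=list(types))
        df.insert(0, "core_id", core_id)
        df.insert(1, "cell_id", sub["cell_id"].to_numpy())
        df["truncated"] = k < n
        frames.append(df)
    if not frames:
        raise ValueError("no core with >= 2 cells")
    out = pd.concat(frames, ignore_index=True)
    return out.set_index(["core_id", "cell_id"])


@dataclass
class NeighborhoodModel:
    """Fitted CN clustering: cohort-level centroids plus per-cell labels."""

    n: int
    tCN: int
    types: tuple[str, ...]
    centroids: np.ndarray  # (tCN, n_types)
    labels: pd.Series  # CN id in 1..tCN, indexed by (core_id, cell_id)
    batch_size: int
    seed: int
    _kmeans: MiniBatchKMeans | None = field(default=None, repr=False)


def cluster_windows(
    windows: pd.DataFrame,
    tCN: int,
    batch_size: int = 1024,
    seed: int = 0,
    n: int | None = None,
) -> NeighborhoodModel:
    """Mini-batch k-means over pooled window vectors (cohort-level CNs).

    Deterministic given the seed; CN ids are 1-based.
    """
    if tCN < 1:
        raise ValueError("tCN must be >= 1")
    types = tuple(c for c in windows.columns if c != "truncated")
    X = windows[list(types)].to_numpy(dtype=float)
    if tCN > len(X):
        raise ValueError(f"tCN={tCN} exceeds the {len(X)} window vectors")
    km = MiniBatchKMeans(
        n_clusters=tCN, batch_size=batch_size, random_state=seed, n_init=3
    )
    labels = km.fit_predict(X) + 1
    return NeighborhoodModel(
        n=n if n is not None else 0,
        tCN=tCN,
        types=types,
        centroids=km.cluster_centers_,
        labels=pd.Series(labels, index=windows.index, name="cn"),
        batch_size=batch_size,
        seed=seed,
        _kmeans=km,
    )


def cn_prevalence(model: NeighborhoodModel, decimals: int | None = None) -> pd.DataFrame:
    """Percent of each core's cells in each CN.

    Raw percentages per core sum to 100 up to float rounding; pass
    ``decimals`` to apply largest-remainder rounding, which makes every
    row sum to exactly 100 at that precision (display convention).
    """
    counts = (
        model.labels.groupby(level="core_id")
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=range(1, model.tCN + 1), fill_value=0)
    )
    pct = counts.div(counts.sum(axis=1), axis=0) * 100.0
    pct.columns = [f"CN{c}" for c in pct.columns]
    if decimals is None:
        return pct
    scale = 10**decimals
    out = np.floor(pct.to_numpy() * scale)
    short = np.round(100 * scale - out.sum(axis=1)).astype(int)
    remainders = pct.to_numpy() * scale - out
    for i, s in enumerate(short):
        if s > 0:
            top = np.argsort(-remainders[i], kind="stable")[:s]
            out[i, top] += 1
    return pd.DataFrame(out / scale, index=pct.index, columns=pct.columns)


def characterize_cns(model: NeighborhoodModel, windows: pd.DataFrame) -> pd.DataFrame:
    """Per-CN mean window composition, 95th-percentile normalized and
    z-scored per type (display normalization for CN heatmaps)."""
    comp = (
        windows[list(model.types)]
        .groupby(model.labels)
        .mean()
        .reindex(range(1, model.tCN + 1))
        .fillna(0.0)
    )
    normed = comp.apply(lambda col: zscore(percentile_normalize(col.to_numpy())), axis=0)
    normed.index = [f"CN{c}" for c in comp.index]
    return normed


def cn_survival_scan(
    prevalence: pd.DataFrame,
    clinical: pd.DataFrame,
    core_to_patient: dict[str, str],
) -> pd.DataFrame:
    """z-stratified log-rank test of every CN's prevalence.

    ``clinical`` must be indexed by patient id with ``survival_time``
    and ``event`` columns.  Patients with several cores get the mean
    prevalence of their cores.  Returns one row per CN with the
    chi-square, p-value and the direction (sign of the high-minus-low
    median survival-time difference is not computed here; the high
    stratum's event count is reported instead).
    """
    per_patient = prevalence.groupby(
        prevalence.index.map(core_to_patient.get)
    ).mean()
    per_patient = per_patient.reindex(clinical.index).dropna()
    rows = []
    for cn in prevalence.columns:
        vals = per_patient[cn]
        sd = vals.std(ddof=1)
        if len(vals) < 2 or not np.isfinite(sd) or sd == 0:
            rows.append({"cn": cn, "chi_square": np.nan, "p_value": np.nan})
            continue
        strat = zscore_stratify(vals)
        hi = strat.index[strat["stratum"] == "high"]
        lo = strat.index[strat["stratum"] == "low"]
        if len(hi) == 0 or len(lo) == 0:
            rows.append({"cn": cn, "chi_square": np.nan, "p_value": np.nan})
            continue
        res = logrank(
            clinical.loc[hi, "survival_time"],
            clinical.loc[hi, "event"],
            clinical.loc[lo, "survival_time"],
            clinical.loc[lo, "event"],
        )
        rows.append(
            {
                "cn": cn,
                "chi_square": res.chi_square,
                "p_value": res.p_value,
                "n_high": len(hi),
                "n_low": len(lo),
                "events_high": int(res.observed[0]),
                "events_low": int(res.observed[1]),
            }
        )
    return pd.DataFrame(rows).set_index("cn")


def sweep(
    table: CellTable,
    clinical: pd.DataFrame,
    core_to_patient: dict[str, str],
    n_values: tuple[int, ...] = tuple(range(3, 31)),
    tCN_values: tuple[int, ...] = (10, 30),
    batch_size: int = 1024,
    seed: int = 0,
    types: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Robustness sweep over window size n and neighbourhood count tCN.

    For each (n, tCN) the CN model is refit and every CN's z-stratified
    log-rank association with survival recorded.  Returns a long frame
    with columns n, tCN, cn, chi_square, p_value.
    """
    rows = []
    for n in n_values:
        windows = window_vectors(table, n=n, types=types)
        for tcn in tCN_values:
            model = cluster_windows(windows, tCN=tcn, batch_size=batch_size, seed=seed, n=n)
            prev = cn_prevalence(model)
            scan = cn_survival_scan(prev, clinical, core_to_patient)
            scan = scan.reset_index()
            scan.insert(0, "n", n)
            scan.insert(1, "tCN", tcn)
            rows.append(scan)
    return pd.concat(rows, ignore_index=True)
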