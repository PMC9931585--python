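"""Permutation-test-based cell-cell interaction and avoidance analysis.

Two cells "interact" when their masks come within ``d`` pixels of each
other (boundary rule; a centroid-distance rule is available as a
fallback).  For every ordered type pair (A, B) the statistic is the
mean, over A cells, of their B-neighbour count.  The null distribution
comes from shuffling the type labels over the fixed cell positions; the
add-one permutation estimator gives

    p_interact = (1 + #{perm >= obs}) / (1 + n_perm)

and symmetrically for avoidance.  A pair is called when the smaller of
the two p-values falls below alpha (0.01 by convention, with 1,000
permutations).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.spatial import cKDTree

from .stacks import SegmentationMap

_TIE_EPS = 1e-9


@dataclass
class AdjacencyGraph:
    core_id: str
    edges: set[tuple[int, int]]  # unordered pairs stored as (min, max)
    rule: str  # "boundary" | "centroid"
    d: float
    cell_ids: tuple[int, ...]

    def degree(self) -> dict[int, int]:
        deg = {cid: 0 for cid in self.cell_ids}
        for a, b in self.edges:
            deg[a] += 1
            deg[b] += 1
        return deg


def build_adjacency(seg: SegmentationMap, d: float = 6.0, rule: str = "boundary") -> AdjacencyGraph:
    """Build the interaction graph of a segmented core.

    boundary rule: edge iff the minimum pixel-to-pixel Euclidean
    distance between the two cells' masks is <= d (inclusive).
    centroid rule: edge iff centroid distance <= d.
    """
    if d <= 0:
        raise ValueError("d must be > 0")
    cells = seg.cells
    ids = [c.cell_id for c in cells]
    edges: set[tuple[int, int]] = set()
    if rule == "boundary":
        rows, cols = np.nonzero(seg.label_raster)
        labs = seg.label_raster[rows, cols]
        pts = np.column_stack([rows, cols]).astype(float)
        tree = cKDTree(pts)
        for i, j in tree.query_pairs(r=d):
            a, b = int(labs[i]), int(labs[j])
            if a != b:
                edges.add((min(a, b), max(a, b)))
    elif rule == "centroid":
        tree = cKDTree(seg.centroids)
        for i, j in tree.query_pairs(r=d):
            edges.add((min(ids[i], ids[j]), max(ids[i], ids[j])))
    else:
        raise ValueError(f"unknown rule {rule!r}")
    return AdjacencyGraph(seg.core_id, edges, rule, float(d), tuple(ids))


@dataclass
class InteractionResult:
    core_id: str
    types: tuple[str, ...]
    observed: np.ndarray  # (t, t) mean B-neighbour count of A cells
    p_interact: np.ndarray
    p_avoid: np.ndarray
    call: np.ndarray  # object array: interaction | avoidance | none | missing
    n_permutations: int
    alpha: float

    def to_frame(self) -> pd.DataFrame:
        rows = []
        t = self.types
        for i, a in enumerate(t):
            for j, b in enumerate(t):
                rows.append(
                    {
                        "core_id": self.core_id,
                        "type_a": a,
                        "type_b": b,
                        "observed": self.observed[i, j],
                        "p_interact": self.p_interact[i, j],
                        "p_avoid": self.p_avoid[i, j],
                        "call": self.call[i, j],
                    }
                )
        return pd.DataFrame(rows)


def _pair_stats(onehot: np.ndarray, adj: sparse.csr_matrix, n_per_type: np.ndarray) -> np.ndarray:
    """Mean B-neighbour count per ordered type pair, NaN for empty A types."""
    totals = onehot.T @ (adj @ onehot)
    with np.errstate(invalid="ignore", divide="ignore"):
        return totals / n_per_type[:, None]


def interaction_test(
    graph: AdjacencyGraph,
    types: pd.Series,
    n_perm: int = 1000,
    alpha: float = 0.01,
    seed: int = 0,
    type_order: tuple[str, ...] | None = None,
) -> InteractionResult:
    """Permutation test for pairwise interaction and avoidance.

    Parameters
    ----------
    graph : AdjacencyGraph
    types : pd.Series
        Cell type label indexed by cell id; must cover the graph's cells.
    n_perm, alpha, seed
        Permutation count, significance level, RNG seed.
    type_order : optional
        Fixed type ordering for the result matrices (default: sorted
        labels present).

    Pairs involving a type with zero cells are reported as missing.
    Labels are shuffled jointly within the core; the statistic depends
    on cell identity only through the labels, so relabelling cell ids
    leaves the result unchanged.
    """
    labels = types.reindex(list(graph.cell_ids))
    if labels.isna().any():
        raise ValueError("types must cover every cell in the graph")
    if type_order is None:
        type_order = tuple(sorted(labels.unique()))
    present = [t for t in type_order if (labels == t).any()]
    if len(present) < 2:
        raise ValueError("need at least 2 cell types present")
    t = len(type_order)
    tindex = {name: k for k, name in enumerate(type_order)}
    y = np.array([tindex[v] for v in labels], dtype=np.int64)
    n = len(y)

    id_pos = {cid: k for k, cid in enumerate(graph.cell_ids)}
    if graph.edges:
        ij = np.array([(id_pos[a], id_pos[b]) for a, b in graph.edges])
        data = np.ones(len(ij))
        adj = sparse.coo_matrix(
            (np.r_[data, data], (np.r_[ij[:, 0], ij[:, 1]], np.r_[ij[:, 1], ij[:, 0]])),
            shape=(n, n),
        ).tocsr()
    else:
        adj = sparse.csr_matrix((n, n))

    def onehot(yv: np.ndarray) -> np.ndarray:
        m = np.zeros((n, t))
        m[np.arange(n), yv] = 1.0
        return m

    n_per_type = np.bincount(y, minlength=t).astype(float)
    obs = _pair_stats(onehot(y), adj, n_per_type)

    rng = np.random.default_rng(seed)
    ge = np.zeros((t, t))
    le = np.zeros((t, t))
    for _ in range(n_perm):
        perm = _pair_stats(onehot(rng.permutation(y)), adj, n_per_type)
        ge += perm >= obs - _TIE_EPS
        le += perm <= obs + _TIE_EPS
    p_int = (1.0 + ge) / (1.0 + n_perm)
    p_avd = (1.0 + le) / (1.0 + n_perm)

    missing = n_per_type == 0
    miss2 = missing[:, None] | missing[None, :]
    p_int[miss2] = np.nan
    p_avd[miss2] = np.nan

    call = np.full((t, t), "none", dtype=object)
    call[(p_int < alpha) & (p_int <= p_avd)] = "interaction"
    call[(p_avd < alpha) & (p_avd < p_int)] = "avoidance"
    call[miss2] = "missing"
    return InteractionResult(
        graph.core_id, type_order, obs, p_int, p_avd, call, n_perm, alpha
    )


def group_heatmap(
    results: list[InteractionResult], groups: dict[str, str]
) -> dict[str, pd.DataFrame]:
    """Aggregate per-core calls into one signed matrix per group.

    Entry (A, B) for a group is the mean over that group's cores of the
    signed call (+1 interaction, -1 avoidance, 0 none); missing pairs
    are excluded from the mean.
    """
    by_group: dict[str, list[InteractionResult]] = {}
    for res in results:
        if res.core_id not in groups:
            raise ValueError(f"core {res.core_id!r} not mapped to a group")
        by_group.setdefault(groups[res.core_id], []).append(res)
    for g in set(groups.values()):
        if g not in by_group:
            raise ValueError(f"group {g!r} has no cores")
    signed = {"interaction": 1.0, "avoidance": -1.0, "none": 0.0, "missing": np.nan}
    out = {}
    for g, ress in by_group.items():
        types = ress[0].types
        stack = np.stack(
            [np.vectorize(signed.get, otypes=[float])(r.call) for r in ress]
        )
        with np.errstate(invalid="ignore"):
            mean = np.nanmean(stack, axis=0)
        out[g] = pd.DataFrame(mean, index=list(types), columns=list(types))
    return out
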