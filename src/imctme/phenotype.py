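"""Majority-vote cell phenotyping.

For each cell, every pixel carries a boolean *presence vector* over the
lineage-marker masks; summing presence vectors over the cell's pixels
gives its *majority vector* M_c (one foreground-pixel count per lineage
marker).  The argmax of M_c selects the winning marker; ties are broken
by the panel's rank priority (lower rank wins) and all-zero cells are
labelled "undefined" rather than forced into a type.  A winning marker
maps to a cell-type label through a configurable rule list, optionally
conditioned on a secondary marker's pixel majority (e.g. CD68 splits
into CD163+ and CD163- macrophages).

Expression is quantified as the raw mean pixel value per channel;
normalization to the 95th percentile (with a z-score companion) is only
for display-style summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .masks import MarkerMask, build_marker_mask
from .panel import MarkerPanel
from .stacks import CellRegion, CoreImageStack, SegmentationMap
from .tables import CellTable

UNDEFINED = "undefined"


@dataclass(frozen=True)
class CombinationRule:
    """Winning marker resolved by a secondary marker's pixel majority.

    If the fraction of the cell's pixels foreground in the secondary
    marker's mask is >= ``threshold`` the cell gets ``pos_label``,
    otherwise ``neg_label``.
    """

    secondary: str
    pos_label: str
    neg_label: str
    threshold: float = 0.5


class TypeRules:
    """Ordered mapping lineage marker -> cell-type label or combination rule."""

    def __init__(self, rules: dict[str, str | CombinationRule]):
        self.rules = dict(rules)

    def __contains__(self, marker: str) -> bool:
        return marker in self.rules

    @property
    def labels(self) -> tuple[str, ...]:
        out: list[str] = []
        for rule in self.rules.values():
            if isinstance(rule, CombinationRule):
                new = [rule.pos_label, rule.neg_label]
            else:
                new = [rule]
            out.extend(l for l in new if l not in out)
        out.append(UNDEFINED)
        return tuple(out)

    def resolve(self, winner: str, secondary_fraction) -> str:
        """Map the winning marker to a label.

        ``secondary_fraction`` is a callable marker -> fraction of the
        cell's pixels foreground in that marker's mask.
        """
        if winner not in self.rules:
            raise KeyError(f"winning marker {winner!r} has no type rule")
        rule = self.rules[winner]
        if isinstance(rule, CombinationRule):
            frac = secondary_fraction(rule.secondary)
            return rule.pos_label if frac >= rule.threshold else rule.neg_label
        return rule


def luad_type_rules() -> TypeRules:
    """Default 17-label rule set for the :func:`~imctme.panel.luad_panel`.

    Monocyte subsets and macrophage CD163 status are resolved by
    secondary-marker pixel majorities.
    """
    return TypeRules(
        {
            "FOXP3": "Treg",
            "CD8a": "Tc",
            "CD4": "Th",
            "CD20": "B cell",
            "CD94": "NK",
            "CD15": "Neutrophil",
            "CD117": "Mast cell",
            "CD68": CombinationRule("CD163", "Mac CD163+", "Mac CD163-", 0.3),
            "CD163": "Mac CD163+",
            "CD14": CombinationRule("CD16", "Int Mo", "Cl Mo", 0.3),
            "CD16": CombinationRule("CD14", "Int Mo", "Non-Cl Mo", 0.3),
            "CD11c": "DC",
            "CD31": "Endothelial",
            "aSMA": "Fibroblast",
            "panCK": "Tumour",
        }
    )


@dataclass
class MajorityVector:
    cell_id: int
    markers: tuple[str, ...]
    counts: np.ndarray  # foreground-pixel count per lineage marker
    n_pixels: int

    def __post_init__(self) -> None:
        if (self.counts < 0).any() or (self.counts > self.n_pixels).any():
            raise ValueError("counts must lie in [0, n_pixels]")


def presence_vector(
    pixel: tuple[int, int], masks: dict[str, MarkerMask], markers: list[str]
) -> np.ndarray:
    """Boolean presence of one pixel across the lineage-marker masks."""
    r, c = pixel
    return np.array([bool(masks[m].mask[r, c]) for m in markers])


def majority_vector(
    cell: CellRegion, masks: dict[str, MarkerMask], markers: list[str]
) -> MajorityVector:
    """Sum of presence vectors over the cell's pixels."""
    missing = [m for m in markers if m not in masks]
    if missing:
        raise ValueError(f"missing mask for marker {missing[0]!r}")
    if len(cell.pixels) == 0:
        raise ValueError(f"cell {cell.cell_id} has no pixels")
    r, c = cell.pixels[:, 0], cell.pixels[:, 1]
    counts = np.array([int(masks[m].mask[r, c].sum()) for m in markers])
    return MajorityVector(cell.cell_id, tuple(markers), counts, len(cell.pixels))


def assign_lineage(mv: MajorityVector, panel: MarkerPanel, type_rules: TypeRules) -> str:
    """Argmax of the majority vector, priority tie-break, rule resolution."""
    counts = mv.counts
    if counts.max() == 0:
        return UNDEFINED
    winners = [m for m, c in zip(mv.markers, counts) if c == counts.max()]
    winner = min(winners, key=panel.priority)
    idx = {m: i for i, m in enumerate(mv.markers)}

    def secondary_fraction(marker: str) -> float:
        if marker not in idx:
            raise KeyError(f"secondary marker {marker!r} not among lineage markers")
        return counts[idx[marker]] / mv.n_pixels

    return type_rules.resolve(winner, secondary_fraction)


def mean_expression(cell: CellRegion, stack: CoreImageStack) -> np.ndarray:
    """Raw mean pixel value of each channel over the cell's pixels."""
    r, c = cell.pixels[:, 0], cell.pixels[:, 1]
    return np.array([stack[name][r, c].mean() for name in stack.channel_names])


def functional_positivity(
    cell: CellRegion, mask: MarkerMask, threshold: float = 0.5
) -> bool:
    """Positive iff the foreground pixel fraction within the cell >= threshold."""
    r, c = cell.pixels[:, 0], cell.pixels[:, 1]
    return bool(mask.mask[r, c].mean() >= threshold)


def percentile_normalize(values: np.ndarray, p: float = 95) -> np.ndarray:
    """Divide by the p-th percentile (linear-interpolation definition)
    and clip at 1.  A zero percentile returns zeros with a warning."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty input")
    q = np.percentile(values, p)
    if q == 0:
        warnings.warn("percentile is zero; returning zeros", stacklevel=2)
        return np.zeros_like(values)
    return np.clip(values / q, None, 1.0)


def zscore(values: np.ndarray) -> np.ndarray:
    """Companion z-score helper for cluster means (sample s.d., ddof=1)."""
    values = np.asarray(values, dtype=float)
    sd = values.std(ddof=1) if values.size > 1 else 0.0
    if sd == 0:
        return np.zeros_like(values)
    return (values - values.mean()) / sd


# ---------------------------------------------------------------------------
# Vectorized per-core phenotyping


def phenotype_core(
    stack: CoreImageStack,
    seg: SegmentationMap,
    panel: MarkerPanel,
    type_rules: TypeRules,
    masks: dict[str, MarkerMask] | None = None,
    positivity_threshold: float = 0.5,
    seed: int | None = None,
) -> CellTable:
    """Build the full cell table for one core.

    Masks for all lineage and functional markers are built from the
    stack unless supplied.  Equivalent to the per-cell operations
    (majority vote, lineage rules, mean expression, positivity) applied
    to every segmented cell, but computed with label-indexed bincounts.
    """
    seg.check_against(stack)
    lineage = panel.lineage_names
    functional = [m for m in panel.functional_names if m in stack.channels]
    if masks is None:
        masks = {}
        for name in lineage + functional:
            if name not in stack.channels:
                raise ValueError(f"missing channel {name!r} for mask construction")
            masks[name] = build_marker_mask(
                stack[name], panel[name].mask_params, marker=name, seed=seed
            )
    lab = seg.label_raster
    max_lab = int(lab.max()) if lab.size else 0
    cells = seg.cells
    ids = np.array([c.cell_id for c in cells], dtype=np.int64)
    n_pixels = np.bincount(lab.ravel(), minlength=max_lab + 1)[ids]

    counts = {}
    for name in lineage + functional:
        bc = np.bincount(lab[masks[name].mask], minlength=max_lab + 1)
        counts[name] = bc[ids]

    count_mat = np.column_stack([counts[m] for m in lineage])
    ranks = np.array([panel.priority(m) for m in lineage])

    labels = []
    for i in range(len(cells)):
        row = count_mat[i]
        if row.max() == 0:
            labels.append(UNDEFINED)
            continue
        tied = np.flatnonzero(row == row.max())
        winner = lineage[tied[np.argmin(ranks[tied])]]
        frac = lambda m: counts[m][i] / n_pixels[i]  # noqa: E731
        labels.append(type_rules.resolve(winner, frac))

    expr = {}
    flat = lab.ravel()
    for name in stack.channel_names:
        sums = np.bincount(flat, weights=stack[name].ravel(), minlength=max_lab + 1)
        expr[f"expr_{name}"] = sums[ids] / n_pixels

    pos = {
        f"pos_{m}": counts[m] / n_pixels >= positivity_threshold for m in functional
    }

    cent = np.array([c.centroid for c in cells]).reshape(-1, 2)
    df = pd.DataFrame(
        {
            "cell_id": ids,
            "core_id": stack.core_id,
            "centroid_row": cent[:, 0],
            "centroid_col": cent[:, 1],
            "lineage": labels,
            **expr,
            **pos,
        }
    )
    return CellTable(
        df,
        lineages=type_rules.labels,
        channels=tuple(stack.channel_names),
        functional=tuple(functional),
    )


def compute_frequencies(
    table: CellTable,
    immune_types: tuple[str, ...] | None = None,
    types: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Per-core cell-type fractions of total cells and, optionally, of
    immune cells.

    Returns a tidy frame indexed by core with one ``freq_total_<type>``
    column per type and, when ``immune_types`` is given,
    ``freq_immune_<type>`` columns over the immune denominator (NaN for
    cores without immune cells).
    """
    if types is None:
        types = table.lineages
    rows = {}
    for core_id in table.core_ids:
        sub = table.for_core(core_id)
        n = len(sub)
        if n == 0:
            raise ValueError(f"core {core_id!r} has zero cells")
        vc = sub["lineage"].value_counts()
        row = {f"freq_total_{t}": vc.get(t, 0) / n for t in types}
        if immune_types is not None:
            n_imm = int(vc.reindex(immune_types).fillna(0).sum())
            for t in immune_types:
                row[f"freq_immune_{t}"] = vc.get(t, 0) / n_imm if n_imm else np.nan
        rows[core_id] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "core_id"
    return out
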