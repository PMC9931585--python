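"""Marker panel definition.

A panel declares, for every antibody channel, whether it is a *lineage*
marker (used to assign cell types), a *functional* marker (used for
positive/negative substates such as Ki-67+ endothelium), or *excluded*
(acquired but not analysed, e.g. channels with inconsistent staining).
Lineage markers additionally carry a rank priority used to break ties in
the majority vote, and every marker carries the parameters of its binary
mask construction.  The panel is plain declarative data: nothing about a
marker is hard-coded elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Literal

Role = Literal["lineage", "functional", "excluded"]


@dataclass(frozen=True)
class MaskParams:
    """Parameters of the five-step marker mask construction.

    Attributes
    ----------
    median_window : int
        Odd side length of the median smoothing window (pixels).
    n_levels : int
        Number of intensity groups the channel is quantized into.
    foreground_level : int
        How many of the brightest intensity groups count as foreground
        (1 = only the brightest group).
    min_blob_area : int
        Connected components (8-connectivity) smaller than this many
        pixels are removed from the mask.
    adaptive_merge : bool
        Whether to intersect the mask with a locally adaptive threshold
        mask as a final refinement step.
    adaptive_sensitivity : float
        Sensitivity of the adaptive threshold, in [0, 1]; higher keeps
        more pixels.
    """

    median_window: int = 3
    n_levels: int = 6
    foreground_level: int = 4
    min_blob_area: int = 2
    adaptive_merge: bool = False
    adaptive_sensitivity: float = 0.4

    def __post_init__(self) -> None:
        if self.median_window < 1 or self.median_window % 2 == 0:
            raise ValueError("median_window must be an odd integer >= 1")
        if self.n_levels < 2:
            raise ValueError("n_levels must be >= 2")
        if not 1 <= self.foreground_level <= self.n_levels:
            raise ValueError("foreground_level must lie in [1, n_levels]")
        if self.min_blob_area < 0:
            raise ValueError("min_blob_area must be >= 0")
        if not 0.0 <= self.adaptive_sensitivity <= 1.0:
            raise ValueError("adaptive_sensitivity must lie in [0, 1]")


@dataclass(frozen=True)
class Marker:
    name: str
    role: Role = "lineage"
    priority_rank: int | None = None
    mask_params: MaskParams = field(default_factory=MaskParams)

    def __post_init__(self) -> None:
        if self.role == "lineage":
            if self.priority_rank is None or self.priority_rank < 1:
                raise ValueError(
                    f"lineage marker {self.name!r} needs a positive priority_rank"
                )


class MarkerPanel:
    """Ordered collection of :class:`Marker` definitions.

    Channel order in the panel is the canonical channel order everywhere
    (multipage TIFF pages, embedding concatenation, ...).
    """

    def __init__(self, markers: list[Marker]):
        names = [m.name for m in markers]
        if len(set(names)) != len(names):
            raise ValueError("marker names must be unique")
        ranks = [m.priority_rank for m in markers if m.role == "lineage"]
        if len(set(ranks)) != len(ranks):
            raise ValueError("lineage priority ranks must be unique")
        self.markers = list(markers)
        self._by_name = {m.name: m for m in markers}

    def __iter__(self) -> Iterator[Marker]:
        return iter(self.markers)

    def __len__(self) -> int:
        return len(self.markers)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __getitem__(self, name: str) -> Marker:
        return self._by_name[name]

    @property
    def names(self) -> list[str]:
        return [m.name for m in self.markers]

    @property
    def lineage_markers(self) -> list[Marker]:
        return [m for m in self.markers if m.role == "lineage"]

    @property
    def lineage_names(self) -> list[str]:
        return [m.name for m in self.markers if m.role == "lineage"]

    @property
    def functional_names(self) -> list[str]:
        return [m.name for m in self.markers if m.role == "functional"]

    def priority(self, name: str) -> int:
        rank = self._by_name[name].priority_rank
        if rank is None:
            raise ValueError(f"{name!r} is not a lineage marker")
        return rank

    def subset(self, names: list[str]) -> "MarkerPanel":
        missing = [n for n in names if n not in self._by_name]
        if missing:
            raise KeyError(f"markers not in panel: {missing}")
        return MarkerPanel([self._by_name[n] for n in names])

    def with_mask_params(self, name: str, **kwargs) -> "MarkerPanel":
        """Return a copy of the panel with one marker's mask parameters
        replaced -- the hook for per-marker mask curation."""
        out = []
        for m in self.markers:
            if m.name == name:
                m = replace(m, mask_params=replace(m.mask_params, **kwargs))
            out.append(m)
        return MarkerPanel(out)


def luad_panel() -> MarkerPanel:
    """Default lung-adenocarcinoma style panel.

    Fifteen lineage markers covering tumour, stromal and immune
    compartments, three functional markers, and four excluded channels
    that mirror markers dropped for inconsistent staining.  Priority
    ranks place highly specific immune markers first and broad
    structural markers last, so that ties resolve toward the more
    specific lineage.
    """

    lineage = [
        # (name, rank)
        ("FOXP3", 1),
        ("CD8a", 2),
        ("CD4", 3),
        ("CD20", 4),
        ("CD94", 5),
        ("CD15", 6),
        ("CD117", 7),
        ("CD68", 8),
        ("CD163", 9),
        ("CD14", 10),
        ("CD16", 11),
        ("CD11c", 12),
        ("CD31", 13),
        ("aSMA", 14),
        ("panCK", 15),
    ]
    markers = [Marker(n, "lineage", r) for n, r in lineage]
    markers += [Marker(n, "functional") for n in ("Ki67", "HIF1a", "pERK")]
    markers += [Marker(n, "excluded") for n in ("GM-CSFR", "PD-1", "PD-L1", "B7-H3")]
    return MarkerPanel(markers)
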