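"""Core image stacks and segmentation maps, with TIFF input/output.

A *core* is one ~1 mm^2 tissue-microarray cylinder imaged at ~1 um/pixel;
its image is one 2-D raster per antibody channel.  Segmentation is
external to this package: a :class:`SegmentationMap` is the contract an
upstream segmenter (or the synthetic generator) must satisfy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .panel import MarkerPanel

log = logging.getLogger(__name__)


class CoreImageStack:
    """Named channel rasters for one core.

    Parameters
    ----------
    core_id : str
    channels : dict[str, np.ndarray]
        Ordered map marker name -> 2-D nonnegative raster.  Insertion
        order is the channel order.
    pixel_size : float
        Micrometres per pixel (default 1.0).
    """

    def __init__(self, core_id: str, channels: dict[str, np.ndarray], pixel_size: float = 1.0):
        if not channels:
            raise ValueError("a stack needs at least one channel")
        shapes = {name: np.asarray(img).shape for name, img in channels.items()}
        first = next(iter(shapes.values()))
        if len(first) != 2:
            raise ValueError("channel rasters must be 2-D")
        for name, shp in shapes.items():
            if shp != first:
                raise ValueError(
                    f"channel {name!r} has shape {shp}, expected {first}"
                )
        self.channels: dict[str, np.ndarray] = {}
        for name, img in channels.items():
            arr = np.asarray(img)
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"channel {name!r} contains non-finite values")
            if arr.min() < 0:
                raise ValueError(f"channel {name!r} contains negative values")
            self.channels[name] = arr
        self.core_id = core_id
        self.pixel_size = float(pixel_size)

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.channels[name]

    def subset(self, names: list[str]) -> "CoreImageStack":
        return CoreImageStack(
            self.core_id, {n: self.channels[n] for n in names}, self.pixel_size
        )


@dataclass
class CellRegion:
    cell_id: int
    pixels: np.ndarray  # (N, 2) int array of (row, col)
    centroid: tuple[float, float]  # (row, col), arithmetic mean of pixels


@dataclass
class SegmentationMap:
    """Label raster (0 = background, k > 0 = cell k) plus derived regions."""

    core_id: str
    label_raster: np.ndarray
    _cells: list[CellRegion] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        lab = np.asarray(self.label_raster)
        if lab.ndim != 2 or not np.issubdtype(lab.dtype, np.integer):
            raise ValueError("label_raster must be a 2-D integer raster")
        if lab.min() < 0:
            raise ValueError("labels must be nonnegative")
        self.label_raster = lab

    @property
    def cells(self) -> list[CellRegion]:
        if self._cells is None:
            lab = self.label_raster
            rows, cols = np.nonzero(lab)
            labs = lab[rows, cols]
            order = np.argsort(labs, kind="stable")
            rows, cols, labs = rows[order], cols[order], labs[order]
            cells = []
            for cid, start, count in zip(
                *np.unique(labs, return_index=True, return_counts=True)
            ):
                px = np.column_stack([rows[start : start + count], cols[start : start + count]])
                cells.append(
                    CellRegion(int(cid), px, (float(px[:, 0].mean()), float(px[:, 1].mean())))
                )
            self._cells = cells
        return self._cells

    @property
    def cell_ids(self) -> np.ndarray:
        return np.array([c.cell_id for c in self.cells])

    @property
    def centroids(self) -> np.ndarray:
        return np.array([c.centroid for c in self.cells]).reshape(-1, 2)

    def check_against(self, stack: CoreImageStack) -> None:
        if self.label_raster.shape != stack.shape:
            raise ValueError(
                f"segmentation shape {self.label_raster.shape} != image shape {stack.shape}"
            )


# ---------------------------------------------------------------------------
# TIFF I/O


def write_core_stack(stack: CoreImageStack, path: str | Path) -> Path:
    """Write a stack as a multipage TIFF, one page per channel in panel order."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = np.stack([np.asarray(img, dtype=np.float32) for img in stack.channels.values()])
    tifffile.imwrite(path, data, photometric="minisblack")
    return path


def read_core_stack(
    path: str | Path, panel: MarkerPanel, core_id: str | None = None, pixel_size: float = 1.0
) -> CoreImageStack:
    """Read a core as a multipage TIFF or a directory of per-marker TIFFs.

    Multipage files are assumed to hold one page per channel in panel
    order.  Directories are expected to hold ``<marker>.tif[f]`` files;
    extra non-panel files are dropped with a warning.  A missing lineage
    channel is a hard error naming the marker.
    """
    path = Path(path)
    if core_id is None:
        core_id = path.stem if path.is_file() else path.name
    channels: dict[str, np.ndarray] = {}
    if path.is_dir():
        available = {}
        for f in sorted(path.iterdir()):
            if f.suffix.lower() in (".tif", ".tiff"):
                available[f.stem] = f
        for name in available:
            if name not in panel:
                log.warning("dropping channel %r: not in panel", name)
        for marker in panel:
            if marker.name in available:
                channels[marker.name] = tifffile.imread(available[marker.name])
            elif marker.role == "lineage":
                raise ValueError(f"missing lineage channel {marker.name!r} in {path}")
    else:
        pages = tifffile.imread(path)
        if pages.ndim == 2:
            pages = pages[None]
        names = panel.names
        if len(pages) < len(names):
            missing = names[len(pages) :]
            lineage_missing = [n for n in missing if panel[n].role == "lineage"]
            if lineage_missing:
                raise ValueError(
                    f"missing lineage channel {lineage_missing[0]!r}: "
                    f"file has {len(pages)} pages for a {len(names)}-marker panel"
                )
        if len(pages) > len(names):
            log.warning(
                "dropping %d trailing non-panel pages", len(pages) - len(names)
            )
        for name, page in zip(names, pages):
            channels[name] = page
    return CoreImageStack(core_id, channels, pixel_size=pixel_size)


def write_segmentation(seg: SegmentationMap, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, seg.label_raster.astype(np.int32))
    return path


def read_segmentation(path: str | Path, core_id: str | None = None) -> SegmentationMap:
    path = Path(path)
    return SegmentationMap(core_id or path.stem, tifffile.imread(path).astype(np.int64))


def write_mask(mask: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, mask.astype(np.uint8))
    return path


def read_mask(path: str | Path) -> np.ndarray:
    return tifffile.imread(Path(path)).astype(bool)
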