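"""Per-marker binary mask construction.

Each antibody channel is turned into a curated binary mask in five
steps: median smoothing, intensity quantization into ``n_levels``
groups, selection of the brightest groups as foreground, removal of
small blobs, and an optional locally adaptive refinement.  The mask is
what downstream phenotyping consumes: a pixel's "presence" for a marker
is simply membership in that marker's mask.

All steps are deterministic.  Quantization is solved exactly (dynamic
programming over the sorted intensity distribution) rather than by
randomized Lloyd iterations, so the whole mask pipeline is a pure
function of (channel, parameters).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .panel import MaskParams

_EIGHT = np.ones((3, 3), dtype=bool)  # 8-connectivity structuring element


@dataclass(frozen=True)
class MarkerMask:
    marker: str
    mask: np.ndarray
    params_used: MaskParams


def median_smooth(channel: np.ndarray, window: int = 3) -> np.ndarray:
    """Median filter with edge replication at the borders."""
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 1")
    channel = np.asarray(channel)
    return ndimage.median_filter(channel, size=window, mode="nearest")


def _kmeans_1d_exact(values: np.ndarray, weights: np.ndarray, k: int) -> np.ndarray:
    """Optimal 1-D weighted k-means: clusters of an optimal solution are
    contiguous in sorted order, so the partition minimizing within-cluster
    sum of squares can be found by dynamic programming.

    Returns the index (into ``values``) of the first element of each
    cluster, length ``k``, clusters ordered by increasing value.
    """
    u = len(values)
    cw = np.concatenate([[0.0], np.cumsum(weights)])
    cwx = np.concatenate([[0.0], np.cumsum(weights * values)])
    cwx2 = np.concatenate([[0.0], np.cumsum(weights * values * values)])

    def seg_cost(i: np.ndarray, j: int) -> np.ndarray:
        # weighted SSE of values[i..j] inclusive, vectorized over i
        w = cw[j + 1] - cw[i]
        s = cwx[j + 1] - cwx[i]
        s2 = cwx2[j + 1] - cwx2[i]
        return s2 - s * s / w

    cost = np.full((k, u), np.inf)
    split = np.zeros((k, u), dtype=np.int64)
    # first row: one cluster covering values[0..j]
    w0, s0, s20 = cw[1:], cwx[1:], cwx2[1:]
    cost[0] = s20 - s0 * s0 / w0
    for kk in range(1, k):
        for j in range(kk, u):
            i = np.arange(kk, j + 1)
            c = cost[kk - 1][i - 1] + seg_cost(i, j)
            a = int(np.argmin(c))
            cost[kk, j] = c[a]
            split[kk, j] = i[a]
    starts = np.empty(k, dtype=np.int64)
    j = u - 1
    for kk in range(k - 1, 0, -1):
        starts[kk] = split[kk, j]
        j = starts[kk] - 1
    starts[0] = 0
    return starts


_MAX_BINS = 2048


def quantize_levels(
    raster: np.ndarray, n_levels: int = 6, seed: int | None = None
) -> np.ndarray:
    """Quantize pixel intensities into ``n_levels`` ordered groups.

    Pixels are clustered in one dimension by exact (dynamic-programming)
    k-means on the intensity distribution; level 1 is the dimmest group
    and level ``n_levels`` the brightest.  Channels with more than 2048
    distinct values are first collapsed onto 2048 quantile bins.  If the
    raster has fewer distinct values than ``n_levels``, the output
    collapses to one level per distinct value, with a warning.

    The ``seed`` argument is accepted for interface stability; the exact
    solver needs no randomness, so the result is independent of it.
    """
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    raster = np.asarray(raster, dtype=np.float64)
    flat = raster.ravel()
    vals, counts = np.unique(flat, return_counts=True)
    if len(vals) <= n_levels:
        if len(vals) < n_levels:
            warnings.warn(
                f"raster has {len(vals)} distinct values < n_levels={n_levels}; "
                "collapsing to one level per value",
                stacklevel=2,
            )
        levels = np.searchsorted(vals, flat) + 1
        return levels.reshape(raster.shape).astype(np.int64)
    if len(vals) > _MAX_BINS:
        # quantile binning of the weighted distribution, then DP on bin means
        edges = np.quantile(flat, np.linspace(0, 1, _MAX_BINS + 1)[1:-1])
        bin_idx = np.searchsorted(edges, vals, side="right")
        nb = bin_idx.max() + 1
        w = np.bincount(bin_idx, weights=counts, minlength=nb)
        wx = np.bincount(bin_idx, weights=counts * vals, minlength=nb)
        keep = w > 0
        reps, wts = wx[keep] / w[keep], w[keep]
        # first original value in each kept bin, for threshold placement
        first_val = np.full(nb, np.inf)
        np.minimum.at(first_val, bin_idx, vals)
        firsts = first_val[keep]
    else:
        reps, wts, firsts = vals, counts.astype(np.float64), vals
    starts = _kmeans_1d_exact(reps, wts, n_levels)
    thresholds = firsts[starts[1:]]  # lower edge of levels 2..n
    levels = np.searchsorted(thresholds, flat, side="right") + 1
    return levels.reshape(raster.shape).astype(np.int64)


def select_foreground(level_raster: np.ndarray, foreground_level: int) -> np.ndarray:
    """Keep the brightest ``foreground_level`` intensity groups.

    A pixel is foreground iff its level >= max_level - foreground_level + 1,
    i.e. ``foreground_level`` counts intensity groups from the brightest
    down (marker signal is bright on a dark background).
    """
    level_raster = np.asarray(level_raster)
    max_level = int(level_raster.max())
    if not 1 <= foreground_level <= max_level:
        raise ValueError(
            f"foreground_level {foreground_level} out of range [1, {max_level}]"
        )
    return level_raster >= max_level - foreground_level + 1


def remove_small_blobs(mask: np.ndarray, min_area: int) -> np.ndarray:
    """Drop 8-connected components with fewer than ``min_area`` pixels."""
    if min_area < 0:
        raise ValueError("min_area must be >= 0")
    mask = np.asarray(mask, dtype=bool)
    if min_area <= 1:
        return mask.copy()
    lab, n = ndimage.label(mask, structure=_EIGHT)
    if n == 0:
        return mask.copy()
    sizes = np.bincount(lab.ravel())
    keep = sizes >= min_area
    keep[0] = False
    return keep[lab]


def adaptive_refine(
    channel: np.ndarray, mask: np.ndarray, sensitivity: float = 0.4, window: int = 15
) -> np.ndarray:
    """Intersect the mask with a locally adaptive threshold mask.

    The local threshold at pixel p is the window mean scaled down in
    proportion to how bright p is relative to the channel maximum:
    ``t(p) = mean_w(p) * (1 - sensitivity * (1 - I(p)/I_max))``.  Bright
    pixels therefore clear the bar more easily; ``sensitivity`` = 0
    reduces to a plain local-mean threshold.  Refinement can only remove
    foreground, never add it.
    """
    if not 0.0 <= sensitivity <= 1.0:
        raise ValueError("sensitivity must lie in [0, 1]")
    channel = np.asarray(channel, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    cmax = channel.max()
    if cmax <= 0:
        return mask.copy()
    local_mean = ndimage.uniform_filter(channel, size=window, mode="nearest")
    threshold = local_mean * (1.0 - sensitivity * (1.0 - channel / cmax))
    return mask & (channel >= threshold)


def build_marker_mask(
    channel: np.ndarray,
    params: MaskParams,
    marker: str = "",
    seed: int | None = None,
) -> MarkerMask:
    """Compose the five mask steps for one channel.

    When quantization collapses to fewer groups than requested (low
    intensity diversity), ``foreground_level`` is clamped so that the
    dimmest realized group stays background; a constant channel (a
    single group) yields an empty mask, since it carries no marker
    signal.
    """
    smooth = median_smooth(channel, params.median_window)
    levels = quantize_levels(smooth, params.n_levels, seed=seed)
    realized = int(levels.max())
    if realized == 1:
        return MarkerMask(
            marker=marker, mask=np.zeros(levels.shape, dtype=bool), params_used=params
        )
    if realized == params.n_levels:
        fg_level = params.foreground_level
    else:
        fg_level = min(params.foreground_level, realized - 1)
    mask = select_foreground(levels, fg_level)
    mask = remove_small_blobs(mask, params.min_blob_area)
    if params.adaptive_merge:
        mask = adaptive_refine(channel, mask, params.adaptive_sensitivity)
    return MarkerMask(marker=marker, mask=mask, params_used=params)
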