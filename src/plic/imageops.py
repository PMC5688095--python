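"""Masks and per-cell feature operators for image cytometry.

Implements the feature vocabulary used by punctum-based gating:

- **morphology mask** -- all pixels within the outermost image contour of a
  designated channel (thresholded foreground, largest component, hole-filled);
- **adaptive-erode mask** -- the largest iteratively eroded version of a base
  mask retaining at least a given percent of its area, used to isolate
  interior (non-membranal) signal;
- **bright-detail image** -- the white top-hat of a channel with a small disk,
  keeping only local bright spots of at most the given radius;
- **BDI** (bright detail intensity) -- summed bright detail inside a mask;
- **Max Pixel** -- largest background-subtracted pixel inside a mask;
- **MCP** (max contour position) -- normalised radial position (0 = centre,
  1 = perimeter) of the concentric ring with the highest mean intensity;
- **BDS** (bright detail similarity) -- Fisher-z transformed Pearson
  correlation of two channels' bright-detail images inside a mask.

All operators accept plain NumPy arrays; masks are boolean pixel sets with
row-major, 0-based coordinates.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.base import BaseEstimator, TransformerMixin

from .core import ROLE_BRIGHTFIELD, ROLE_PLA, CellImage

__all__ = [
    "morphology_mask",
    "adaptive_erode_mask",
    "bright_detail_image",
    "bright_detail_intensity",
    "max_pixel",
    "estimate_background",
    "staining_area",
    "max_contour_position",
    "bright_detail_similarity",
    "FeatureConfig",
    "compute_features",
    "extract_features",
    "FeatureExtractor",
]


@lru_cache(maxsize=None)
def _disk_footprint(radius: int) -> np.ndarray:
    r = int(radius)
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return (yy**2 + xx**2 <= r**2)


#: 4-connected structuring element used for the adaptive erosion.
_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], bool)


def morphology_mask(grid: np.ndarray, threshold="otsu") -> np.ndarray:
    """All pixels within the outermost contour of the thresholded foreground.

    The grid is thresholded (Otsu by default, or a fixed numeric threshold),
    the largest 4-connected foreground component is kept, and interior holes
    are filled so that everything inside the outermost contour is included.

    A constant grid has no contour: an empty mask is returned with a warning.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.max() == grid.min():
        warnings.warn("constant image has no contour; returning empty mask",
                      stacklevel=2)
        return np.zeros(grid.shape, dtype=bool)
    if threshold == "otsu":
        from skimage.filters import threshold_otsu

        thr = threshold_otsu(grid)
    else:
        thr = float(threshold)
    fg = grid > thr
    if not fg.any():
        warnings.warn("thresholding left no foreground; returning empty mask",
                      stacklevel=2)
        return fg
    labels, n = ndimage.label(fg)  # 4-connectivity
    if n > 1:
        sizes = np.bincount(labels.ravel())
        sizes[0] = 0
        fg = labels == int(np.argmax(sizes))
    return ndimage.binary_fill_holes(fg)


def adaptive_erode_mask(base: np.ndarray, percent: float) -> np.ndarray:
    """Largest iteratively eroded version of ``base`` with area >= percent%.

    Erosion proceeds with a 4-connected structuring element, so the retained
    core follows the shape of the base mask.  ``percent=100`` returns the
    base unchanged; ``percent=0`` returns the last non-empty erosion (the
    shape's inner core).  The result is always a subset of ``base``.
    """
    if not 0 <= percent <= 100:
        raise ValueError("percent must be in [0, 100]")
    base = np.asarray(base, dtype=bool)
    area0 = int(base.sum())
    if area0 == 0:
        warnings.warn("adaptive erosion of an empty mask", stacklevel=2)
        return base.copy()
    target = percent / 100.0 * area0
    current = base.copy()
    while True:
        eroded = ndimage.binary_erosion(current, structure=_CROSS)
        area = int(eroded.sum())
        if area == 0 or area < target:
            return current
        current = eroded


def bright_detail_image(grid: np.ndarray, radius: int = 3) -> np.ndarray:
    """Local bright detail: the white top-hat by a disk of ``radius`` pixels.

    Subtracts the morphological opening, leaving only bright features whose
    support is smaller than the disk; the result is everywhere >= 0.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    grid = np.asarray(grid, dtype=float)
    return ndimage.white_tophat(grid, footprint=_disk_footprint(radius))


def bright_detail_intensity(grid, mask, radius: int = 3) -> float:
    """Summed bright detail (top-hat) intensity inside ``mask``."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != np.shape(grid):
        raise ValueError("mask shape must match the grid")
    if not mask.any():
        warnings.warn("BDI of an empty mask is 0", stacklevel=2)
        return 0.0
    return float(bright_detail_image(grid, radius)[mask].sum())


def estimate_background(grid: np.ndarray, mask: np.ndarray) -> float:
    """Background level: the mode of the out-of-mask pixels.

    When the out-of-mask pixels have no repeated value (generic float images)
    or the mask covers the whole grid, falls back to the mean of the lowest
    decile of the available pixels.
    """
    grid = np.asarray(grid, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    out = grid[~mask]
    if out.size == 0:
        out = grid[mask]
    if out.size == 0:
        return 0.0
    vals, counts = np.unique(out, return_counts=True)
    if counts.max() > 1:
        return float(vals[np.argmax(counts)])
    lo = np.sort(out)[: max(1, out.size // 10)]
    return float(lo.mean())


def max_pixel(grid, mask, background="mode") -> float:
    """Largest background-subtracted pixel value inside ``mask``, >= 0.

    ``background`` is either the policy ``"mode"`` (see
    :func:`estimate_background`) or an explicit numeric level.
    """
    grid = np.asarray(grid, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != grid.shape:
        raise ValueError("mask shape must match the grid")
    if not mask.any():
        warnings.warn("Max Pixel of an empty mask is 0", stacklevel=2)
        return 0.0
    bg = estimate_background(grid, mask) if background == "mode" else float(background)
    return float(max(grid[mask].max() - bg, 0.0))


def staining_area(grid, mask, fraction: float = 0.25, background="mode") -> float:
    """Area (pixels) of the stained region inside ``mask``.

    A pixel belongs to the stained region when its background-subtracted
    intensity reaches ``fraction`` of the cell's Max Pixel.  Compact puncta
    therefore yield small areas while diffuse elevation covers most of the
    mask.  Returns 0 for an empty mask or a signal-free cell.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    grid = np.asarray(grid, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return 0.0
    bg = estimate_background(grid, mask) if background == "mode" else float(background)
    vals = grid[mask] - bg
    peak = vals.max()
    if peak <= 0:
        return 0.0
    return float(np.count_nonzero(vals >= fraction * peak))


def max_contour_position(grid, mask, n_rings: int = 8) -> float:
    """Normalised radial position of the ring with highest mean intensity.

    The mask is partitioned into ``n_rings`` concentric rings by the Euclidean
    distance transform (distance to the mask boundary, normalised so 0 is the
    innermost point and 1 the perimeter).  The midpoint of the ring with the
    highest mean intensity per pixel is returned; ties resolve to the
    innermost ring.  Returns NaN (missing feature) for an empty mask.
    """
    if n_rings < 2:
        raise ValueError("n_rings must be >= 2")
    grid = np.asarray(grid, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        warnings.warn("MCP of an empty mask is undefined", stacklevel=2)
        return float("nan")
    dist = ndimage.distance_transform_edt(mask)
    dmax = dist.max()
    pos = 1.0 - dist[mask] / dmax if dmax > 0 else np.zeros(int(mask.sum()))
    ring = np.clip((pos * n_rings).astype(int), 0, n_rings - 1)
    sums = np.bincount(ring, weights=grid[mask], minlength=n_rings)
    counts = np.bincount(ring, minlength=n_rings)
    means = np.full(n_rings, -np.inf)
    np.divide(sums, counts, out=means, where=counts > 0)
    best = int(np.argmax(means))
    return (best + 0.5) / n_rings


def bright_detail_similarity(
    grid_a, grid_b, mask, radius: int = 3, clip: float = 0.999
) -> float:
    """Fisher-z transformed Pearson correlation of two bright-detail images.

    Both channels are top-hat filtered (radius <= ``radius`` bright spots),
    correlated over the mask pixels, and the correlation is mapped through
    ``0.5 * ln((1 + r) / (1 - r))`` after clipping ``r`` to ``+/- clip``.
    High values flag strong bright-spot overlay between the channels (e.g.
    uncompensatable bleed-through).  Zero-variance input in either channel
    yields 0; a mask of fewer than 3 pixels is a missing feature (NaN).
    """
    mask = np.asarray(mask, dtype=bool)
    if np.shape(grid_a) != np.shape(grid_b) or mask.shape != np.shape(grid_a):
        raise ValueError("grids and mask must share one shape")
    if mask.sum() < 3:
        warnings.warn("BDS needs at least 3 mask pixels", stacklevel=2)
        return float("nan")
    x = bright_detail_image(grid_a, radius)[mask]
    y = bright_detail_image(grid_b, radius)[mask]
    if x.std() == 0 or y.std() == 0:
        warnings.warn("zero-variance bright detail; BDS set to 0", stacklevel=2)
        return 0.0
    r = float(np.corrcoef(x, y)[0, 1])
    r = float(np.clip(r, -clip, clip))
    return float(np.arctanh(r))


# ---------------------------------------------------------------------------
# Batched per-cell feature extraction


@dataclass
class FeatureConfig:
    """How per-cell features are computed.

    ``mask_channel``
        Channel whose morphology mask segments the cell (default: the first
        brightfield-role channel).
    ``heavy_channels``
        Channels receiving the full punctum feature set (default: the
        PLA-role channels); every channel always gets total/mean intensity.
    ``bds_pairs``
        Channel pairs for bright-detail similarity (default: each PLA channel
        against its spectrally adjacent channel in acquisition order).
    """

    mask_channel: Optional[str] = None
    threshold: object = "otsu"
    bd_radius: int = 3
    adaptive_erode_percent: float = 78.0
    n_rings: int = 8
    area_fraction: float = 0.25
    heavy_channels: Optional[Sequence[str]] = None
    bds_pairs: Optional[Sequence] = None

    def resolve(self, cell: CellImage) -> "FeatureConfig":
        """Fill channel-dependent defaults from a cell's manifest."""
        mask_channel = self.mask_channel
        if mask_channel is None:
            bf = cell.channels_with_role(ROLE_BRIGHTFIELD)
            if not bf:
                raise ValueError("no brightfield channel to seed the mask; "
                                 "set FeatureConfig.mask_channel")
            mask_channel = bf[0]
        heavy = self.heavy_channels
        if heavy is None:
            heavy = tuple(cell.channels_with_role(ROLE_PLA))
        pairs = self.bds_pairs
        if pairs is None:
            pairs = []
            names = cell.channel_names
            for ch in cell.channels_with_role(ROLE_PLA):
                i = names.index(ch)
                j = i + 1 if i + 1 < len(names) else i - 1
                pairs.append((ch, names[j]))
        for ch in (mask_channel, *heavy):
            if ch not in cell.channel_names:
                raise KeyError(f"channel {ch!r} not present in cell")
        return FeatureConfig(
            mask_channel=mask_channel,
            threshold=self.threshold,
            bd_radius=self.bd_radius,
            adaptive_erode_percent=self.adaptive_erode_percent,
            n_rings=self.n_rings,
            area_fraction=self.area_fraction,
            heavy_channels=tuple(heavy),
            bds_pairs=tuple((a, b) for a, b in pairs),
        )


def compute_features(
    cell: CellImage,
    config: Optional[FeatureConfig] = None,
    _tophats: Optional[dict] = None,
) -> dict:
    """Compute the full per-cell feature vector.

    Returns a flat dict with keys ``{channel}_total``, ``{channel}_mean`` for
    every channel; ``{channel}_bdi``, ``{channel}_max_pixel``,
    ``{channel}_mcp``, ``{channel}_area`` plus the adaptive-erode variants
    ``{channel}_bdi_erode`` and ``{channel}_max_pixel_erode`` for the heavy
    channels; ``BDS_{a}_{b}`` per configured pair; and the mask areas.
    Missing features (empty masks, degenerate input) are NaN, never silently
    zeroed.
    """
    cfg = (config or FeatureConfig()).resolve(cell)
    feats: dict = {}

    mask = morphology_mask(cell.channel(cfg.mask_channel), cfg.threshold)
    emask = adaptive_erode_mask(mask, cfg.adaptive_erode_percent) if mask.any() else mask
    feats["mask_area"] = float(mask.sum())
    feats["erode_area"] = float(emask.sum())

    tophats: dict = dict(_tophats) if _tophats else {}

    def tophat(ch: str) -> np.ndarray:
        if ch not in tophats:
            tophats[ch] = bright_detail_image(cell.channel(ch), cfg.bd_radius)
        return tophats[ch]

    empty = not mask.any()
    for ch in cell.channel_names:
        grid = cell.channel(ch)
        if empty:
            feats[f"{ch}_total"] = float("nan")
            feats[f"{ch}_mean"] = float("nan")
        else:
            total = float(grid[mask].sum())
            feats[f"{ch}_total"] = total
            feats[f"{ch}_mean"] = total / feats["mask_area"]

    for ch in cfg.heavy_channels:
        grid = cell.channel(ch)
        if empty:
            for suffix in ("bdi", "max_pixel", "mcp", "area",
                           "bdi_erode", "max_pixel_erode"):
                feats[f"{ch}_{suffix}"] = float("nan")
            continue
        bg = estimate_background(grid, mask)
        th = tophat(ch)
        feats[f"{ch}_bdi"] = float(th[mask].sum())
        feats[f"{ch}_max_pixel"] = float(max(grid[mask].max() - bg, 0.0))
        feats[f"{ch}_mcp"] = max_contour_position(grid, mask, cfg.n_rings)
        feats[f"{ch}_area"] = staining_area(grid, mask, cfg.area_fraction,
                                            background=bg)
        if emask.any():
            feats[f"{ch}_bdi_erode"] = float(th[emask].sum())
            feats[f"{ch}_max_pixel_erode"] = float(max(grid[emask].max() - bg, 0.0))
        else:
            feats[f"{ch}_bdi_erode"] = float("nan")
            feats[f"{ch}_max_pixel_erode"] = float("nan")

    for a, b in cfg.bds_pairs:
        if empty:
            feats[f"BDS_{a}_{b}"] = float("nan")
            continue
        x = tophat(a)[mask]
        y = tophat(b)[mask]
        if mask.sum() < 3:
            feats[f"BDS_{a}_{b}"] = float("nan")
        elif x.std() == 0 or y.std() == 0:
            feats[f"BDS_{a}_{b}"] = 0.0
        else:
            r = float(np.clip(np.corrcoef(x, y)[0, 1], -0.999, 0.999))
            feats[f"BDS_{a}_{b}"] = float(np.arctanh(r))
    return feats


def extract_features(
    cells: Sequence[CellImage], config: Optional[FeatureConfig] = None
) -> pd.DataFrame:
    """Feature table for a sample: one row per cell, ``cell_id`` index.

    Numerically identical to calling :func:`compute_features` per cell; when
    all cells share one geometry the bright-detail (top-hat) filtering is
    batched over the whole sample in a single stacked call, which is the only
    performance-relevant difference.
    """
    config = config or FeatureConfig()
    cells = list(cells)
    if not cells:
        df = pd.DataFrame()
        df.index.name = "cell_id"
        return df

    batched_tophats = None
    same_geometry = all(
        c.shape == cells[0].shape and c.channel_names == cells[0].channel_names
        for c in cells
    )
    if same_geometry and len(cells) > 1:
        cfg0 = config.resolve(cells[0])
        need = set(cfg0.heavy_channels)
        for a, b in cfg0.bds_pairs:
            need.update((a, b))
        fp = _disk_footprint(cfg0.bd_radius)[None, :, :]
        batched_tophats = {}
        for ch in sorted(need):
            stack = np.stack([c.channel(ch) for c in cells])
            th = ndimage.white_tophat(stack, footprint=fp)
            batched_tophats[ch] = th

    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # empty-mask cells are NaN-flagged rows
        for i, cell in enumerate(cells):
            pre = (
                {ch: th[i] for ch, th in batched_tophats.items()}
                if batched_tophats is not None
                else None
            )
            rows.append(compute_features(cell, config, _tophats=pre))
    df = pd.DataFrame(rows)
    df.index.name = "cell_id"
    return df


class FeatureExtractor(BaseEstimator, TransformerMixin):
    """Stateless transformer turning cell images into a feature table.

    scikit-learn compatible: ``fit`` is a no-op, ``transform`` maps a
    sequence of :class:`~plic.core.CellImage` to a DataFrame with one row per
    cell.  Parameters mirror :class:`FeatureConfig`.
    """

    def __init__(
        self,
        mask_channel=None,
        threshold="otsu",
        bd_radius=3,
        adaptive_erode_percent=78.0,
        n_rings=8,
        area_fraction=0.25,
        heavy_channels=None,
        bds_pairs=None,
    ):
        self.mask_channel = mask_channel
        self.threshold = threshold
        self.bd_radius = bd_radius
        self.adaptive_erode_percent = adaptive_erode_percent
        self.n_rings = n_rings
        self.area_fraction = area_fraction
        self.heavy_channels = heavy_channels
        self.bds_pairs = bds_pairs

    def _config(self) -> FeatureConfig:
        return FeatureConfig(
            mask_channel=self.mask_channel,
            threshold=self.threshold,
            bd_radius=self.bd_radius,
            adaptive_erode_percent=self.adaptive_erode_percent,
            n_rings=self.n_rings,
            area_fraction=self.area_fraction,
            heavy_channels=self.heavy_channels,
            bds_pairs=self.bds_pairs,
        )

    def fit(self, X, y=None):
        return self

    def transform(self, X) -> pd.DataFrame:
        return extract_features(X, self._config())
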