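"""Spillover estimation from single-stain controls and linear unmixing.

Fluorophores bleed into neighbouring detection channels roughly linearly, so
an observed pixel vector is ``observed = true @ S`` for a K x K spillover
matrix ``S`` (rows = source channel, columns = detected channel, unit
diagonal).  ``S`` is estimated from single-stain controls -- one sample per
channel with dye present in that channel only -- as the per-cell median of
off-channel to source-channel intensity ratios, and inverted pixelwise to
compensate images before feature extraction.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .core import CellImage
from .imageops import morphology_mask

__all__ = [
    "SpilloverMatrix",
    "SpilloverEstimationError",
    "estimate_spillover",
    "compensate",
    "compensate_sample",
    "SpilloverCompensator",
]


class SpilloverEstimationError(RuntimeError):
    """Raised when a control sample cannot support spillover estimation."""


@dataclass(frozen=True)
class SpilloverMatrix:
    """Unitless channel mixing coefficients; rows = source, cols = detected."""

    matrix: np.ndarray
    channels: tuple

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "channels", tuple(self.channels))
        k = len(self.channels)
        if m.shape != (k, k):
            raise ValueError("matrix must be K x K with one row per channel")
        if not np.allclose(np.diag(m), 1.0):
            raise ValueError("spillover diagonal must be 1")
        off = m[~np.eye(k, dtype=bool)]
        if off.size and (off.min() < 0 or off.max() >= 1):
            raise ValueError("off-diagonal spillover must lie in [0, 1)")
        object.__setattr__(self, "matrix", m)

    def condition_number(self) -> float:
        return float(np.linalg.cond(self.matrix))

    def validate(self, cond_limit: float = 1e6) -> "SpilloverMatrix":
        if not np.isfinite(self.condition_number()) or self.condition_number() > cond_limit:
            raise ValueError(
                f"spillover matrix is ill-conditioned "
                f"(cond={self.condition_number():.3g} > {cond_limit:g})"
            )
        return self

    @classmethod
    def identity(cls, channels: Sequence[str]) -> "SpilloverMatrix":
        return cls(np.eye(len(tuple(channels))), tuple(channels))

    def to_csv(self, path) -> None:
        pd.DataFrame(self.matrix, index=list(self.channels),
                     columns=list(self.channels)).to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "SpilloverMatrix":
        df = pd.read_csv(path, index_col=0)
        if list(df.index) != list(df.columns):
            raise ValueError("spillover CSV must have matching row/column channels")
        return cls(df.to_numpy(dtype=float), tuple(df.columns))


def estimate_spillover(
    controls: Mapping[str, Sequence[CellImage]],
    intensity_floor: float = 10.0,
    cond_limit: float = 1e6,
) -> SpilloverMatrix:
    """Estimate the spillover matrix from single-stain control samples.

    ``controls`` maps each source channel name to its control cells.  For each
    control cell the cell region is segmented on the *source* channel (that is
    the only channel guaranteed to carry signal) and the ratio of every
    channel's in-mask summed intensity to the source channel's is computed.
    Row ``k`` of the matrix is the per-cell median of those ratios, with the
    diagonal forced to 1.  Cells whose source-channel mean intensity falls
    below ``intensity_floor`` are excluded as zero-signal events.

    Raises :class:`SpilloverEstimationError` when a control contributes no
    usable cell.
    """
    if not controls:
        raise SpilloverEstimationError("no control samples given")
    first = next(iter(controls.values()))
    if not first:
        raise SpilloverEstimationError("empty control sample")
    channels = first[0].channel_names
    k = len(channels)
    matrix = np.eye(k)
    for src_name, cells in controls.items():
        src = channels.index(src_name)
        ratios = []
        for cell in cells:
            grid = cell.channel(src_name)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                mask = morphology_mask(grid)
            if not mask.any():
                continue
            src_sum = float(grid[mask].sum())
            if src_sum / mask.sum() < intensity_floor:
                continue
            ratios.append(cell.pixels[:, mask].sum(axis=1) / src_sum)
        if not ratios:
            raise SpilloverEstimationError(
                f"control for channel {src_name!r} has no cell above the "
                f"intensity floor"
            )
        row = np.median(np.vstack(ratios), axis=0)
        row[src] = 1.0
        matrix[src] = np.clip(row, 0.0, np.nextafter(1.0, 0.0))
        matrix[src, src] = 1.0
    return SpilloverMatrix(matrix, channels).validate(cond_limit)


def compensate(
    cell: CellImage, spillover: SpilloverMatrix, cond_limit: float = 1e6
) -> CellImage:
    """Pixelwise linear unmixing: solve ``observed = true @ S`` per pixel.

    Negative solutions (noise pushed below zero) are floored at 0; channel
    names and roles are preserved.
    """
    if tuple(spillover.channels) != tuple(cell.channel_names):
        raise ValueError("spillover channels do not match the cell's channels")
    spillover.validate(cond_limit)
    k, h, w = cell.pixels.shape
    observed = cell.pixels.reshape(k, -1)
    # observed_c = sum_s true_s * S[s, c]  =>  S^T @ true = observed
    true = np.linalg.solve(spillover.matrix.T, observed)
    return cell.with_pixels(np.clip(true, 0.0, None).reshape(k, h, w))


def compensate_sample(
    cells: Sequence[CellImage], spillover: SpilloverMatrix, cond_limit: float = 1e6
) -> list:
    spillover.validate(cond_limit)
    return [compensate(c, spillover, cond_limit) for c in cells]


class SpilloverCompensator(BaseEstimator, TransformerMixin):
    """scikit-learn style transformer around spillover estimation/unmixing.

    ``fit`` accepts either a mapping of channel name to single-stain control
    cells (the matrix is estimated) or nothing when ``matrix`` was given at
    construction.  ``transform`` unmixes a sequence of cells.
    """

    def __init__(self, matrix: SpilloverMatrix | None = None,
                 intensity_floor: float = 10.0, cond_limit: float = 1e6):
        self.matrix = matrix
        self.intensity_floor = intensity_floor
        self.cond_limit = cond_limit

    def fit(self, X=None, y=None):
        if self.matrix is not None:
            self.spillover_ = self.matrix.validate(self.cond_limit)
        elif X:
            self.spillover_ = estimate_spillover(
                X, intensity_floor=self.intensity_floor, cond_limit=self.cond_limit
            )
        else:
            raise ValueError("either a matrix or single-stain controls required")
        return self

    def transform(self, X) -> list:
        if not hasattr(self, "spillover_"):
            raise ValueError("SpilloverCompensator is not fitted")
        return compensate_sample(X, self.spillover_, self.cond_limit)
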