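"""Core data containers shared across the pipeline.

A single cellular event acquired by imaging flow cytometry is a small
multichannel pixel grid (one image per detection channel).  Channels carry a
*role* -- brightfield proxy, PLA (proximity ligation assay) signal, or a
surface/intracellular marker stain -- which downstream modules use to decide
which channel seeds the segmentation mask, which channel carries the punctate
rolling-circle-amplification signal, and which channels define populations.
"""
from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

ROLE_BRIGHTFIELD = "brightfield"
ROLE_PLA = "pla"
ROLE_MARKER = "marker"
VALID_ROLES = (ROLE_BRIGHTFIELD, ROLE_PLA, ROLE_MARKER)

#: Label used for cells that cannot be assigned to any population.
UNASSIGNED = "UNASSIGNED"


class CellClass(str, Enum):
    """Planted signal morphology of a simulated cell.

    ``NUCLEAR_PLA_POS``
        true proximity events: compact bright puncta inside the nucleus
        ("nuclear speckle" pattern).
    ``MEMBRANAL_FP``
        nonspecific probe binding: puncta straddling the plasma membrane.
    ``DIFFUSE_AF``
        autofluorescent cell: diffuse, textured elevation across the whole
        cell body.
    ``NEGATIVE``
        no planted PLA-channel signal (read noise only).
    """

    NUCLEAR_PLA_POS = "NUCLEAR_PLA_POS"
    MEMBRANAL_FP = "MEMBRANAL_FP"
    DIFFUSE_AF = "DIFFUSE_AF"
    NEGATIVE = "NEGATIVE"


class Population(str, Enum):
    """Marker-defined population of a cell.

    ``TARGET_HI`` / ``TARGET_LO`` are the CD80-high / CD80-low subsets of the
    marker-positive target population (the mTEC-like rare population);
    ``CONTROL_POP`` is the CD45-positive negative-control population.
    """

    TARGET_HI = "TARGET_HI"
    TARGET_LO = "TARGET_LO"
    CONTROL_POP = "CONTROL_POP"


@dataclass(frozen=True)
class CellImage:
    """Multichannel pixel grid for one cellular event.

    Parameters
    ----------
    pixels : ndarray of shape (n_channels, h, w)
        Nonnegative, finite intensities.
    channel_names : tuple of str
        One name per channel, unique.
    roles : tuple of str
        One role per channel, drawn from :data:`VALID_ROLES`.
    """

    pixels: np.ndarray
    channel_names: tuple
    roles: tuple

    def __post_init__(self):
        object.__setattr__(self, "channel_names", tuple(self.channel_names))
        object.__setattr__(self, "roles", tuple(self.roles))
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 3:
            raise ValueError("pixels must have shape (n_channels, h, w)")
        if px.shape[0] != len(self.channel_names):
            raise ValueError("one channel name required per channel")
        if len(self.roles) != len(self.channel_names):
            raise ValueError("one role required per channel")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        for role in self.roles:
            if role not in VALID_ROLES:
                raise ValueError(f"unknown channel role {role!r}")
        if not np.all(np.isfinite(px)):
            raise ValueError("pixel intensities must be finite")
        if px.min() < 0:
            raise ValueError("pixel intensities must be >= 0")
        object.__setattr__(self, "pixels", px)

    @property
    def n_channels(self) -> int:
        return self.pixels.shape[0]

    @property
    def shape(self) -> tuple:
        """(h, w) of every channel grid."""
        return self.pixels.shape[1:]

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"no channel named {name!r}") from None

    def channel(self, name: str) -> np.ndarray:
        """Pixel grid of the named channel (a view, do not mutate)."""
        return self.pixels[self.channel_index(name)]

    def channels_with_role(self, role: str) -> list:
        """Names of all channels carrying ``role``, in acquisition order."""
        return [n for n, r in zip(self.channel_names, self.roles) if r == role]

    def with_pixels(self, pixels: np.ndarray) -> "CellImage":
        """New :class:`CellImage` with the same channel metadata."""
        return CellImage(pixels, self.channel_names, self.roles)
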