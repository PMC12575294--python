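"""Shared domain types: pixel calibration and multichannel micrographs.

Coordinates are 0-based ``(row, col)`` throughout the package. Intensities
are 16-bit counts (0-65535), the native bit depth of the tiled confocal
panels this pipeline was designed for.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger("mfquant")

#: canonical channel labels
CHAN_POST = "postsynaptic"
CHAN_PRE = "presynaptic"
CHAN_MF = "mossy_fiber"
CHAN_NUC = "nuclear"

UINT16_MAX = 65535


class ParameterError(ValueError):
    """A generation or detection parameter is out of its valid range."""


class ChannelError(KeyError):
    """A required channel is missing from a micrograph."""


class DegenerateInputError(ValueError):
    """Input is degenerate for the requested statistic (e.g. zero variance)."""


@dataclass(frozen=True)
class PixelScale:
    """Linear pixel calibration in microns per pixel.

    The default corresponds to tiled panels of roughly 8,000 x 10,000 px
    spanning ~350 x 420 um, i.e. 0.04375 x 0.042 um/px, under which a
    ~200-px punctum has an area of ~0.37 um^2.
    """

    microns_per_px_x: float = 350.0 / 8000.0
    microns_per_px_y: float = 420.0 / 10000.0

    def __post_init__(self) -> None:
        if not (self.microns_per_px_x > 0 and self.microns_per_px_y > 0):
            raise ParameterError("pixel scale must be strictly positive")

    @property
    def pixel_area_um2(self) -> float:
        return self.microns_per_px_x * self.microns_per_px_y


DEFAULT_PIXEL_SCALE = PixelScale()


@dataclass
class Micrograph:
    """A named multichannel 2D raster of 16-bit intensity counts.

    pixels
        Array of shape ``(n_channels, rows, cols)``, dtype uint16.
    channel_names
        One label per channel, e.g. ``("postsynaptic", "presynaptic")``.
    """

    pixels: np.ndarray
    channel_names: tuple[str, ...]
    pixel_scale: PixelScale = field(default_factory=PixelScale)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim == 2:
            self.pixels = self.pixels[None]
        if self.pixels.ndim != 3:
            raise ParameterError("pixels must be (channels, rows, cols)")
        self.channel_names = tuple(self.channel_names)
        if len(self.channel_names) != self.pixels.shape[0]:
            raise ParameterError(
                f"{len(self.channel_names)} channel names for "
                f"{self.pixels.shape[0]} channel planes"
            )
        if self.pixels.min() < 0 or self.pixels.max() > UINT16_MAX:
            raise ParameterError("intensities outside 16-bit range")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[1:]

    def channel(self, name: str) -> np.ndarray:
        """Return one channel plane by label."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise ChannelError(
                f"channel {name!r} not in {self.channel_names}"
            ) from None
        return self.pixels[idx]

    def has_channel(self, name: str) -> bool:
        return name in self.channel_names
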