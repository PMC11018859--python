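"""In-memory containers for multi-channel whole-slide images.

Coordinate convention: pixel-index origin at top-left, axes (row, col);
physical coordinates are index * pixel_size with pixel-center semantics.
Pixels are isotropic (one µm-per-pixel scalar per experiment).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ChannelImage", "RoundStack", "HyperplexStack"]


@dataclass
class ChannelImage:
    """One fluorescence channel of one imaging round.

    Parameters
    ----------
    pixels : ndarray, shape (rows, cols)
        Non-negative intensities in 16-bit unsigned range.
    pixel_size : float
        Isotropic pixel size in µm per pixel.
    channel_name : str
        Marker identifier (e.g. ``"DAPI"``, ``"GFP"``).
    round_index : int
        Zero-based imaging-round index.
    """

    pixels: np.ndarray
    pixel_size: float
    channel_name: str = ""
    round_index: int = 0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2D array")
        if np.issubdtype(self.pixels.dtype, np.floating) and not np.all(
            np.isfinite(self.pixels)
        ):
            raise ValueError("pixels must be finite")
        if self.pixels.size and self.pixels.min() < 0:
            raise ValueError("pixels must be non-negative")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def with_pixels(self, pixels: np.ndarray) -> "ChannelImage":
        """Copy of this channel with replaced pixel data."""
        return ChannelImage(
            pixels=pixels,
            pixel_size=self.pixel_size,
            channel_name=self.channel_name,
            round_index=self.round_index,
        )


@dataclass
class RoundStack:
    """All channels of one imaging round, sharing shape and pixel size."""

    channels: list[ChannelImage]
    dapi_index: int = 0

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("round must contain at least one channel")
        shapes = {c.shape for c in self.channels}
        if len(shapes) != 1:
            raise ValueError(f"channels differ in shape: {shapes}")
        sizes = {c.pixel_size for c in self.channels}
        if len(sizes) != 1:
            raise ValueError("channels differ in pixel size")
        if not 0 <= self.dapi_index < len(self.channels):
            raise ValueError("dapi_index out of range")

    @property
    def dapi(self) -> ChannelImage:
        return self.channels[self.dapi_index]

    @property
    def shape(self) -> tuple[int, int]:
        return self.channels[0].shape

    @property
    def pixel_size(self) -> float:
        return self.channels[0].pixel_size

    @property
    def channel_names(self) -> list[str]:
        return [c.channel_name for c in self.channels]

    def __len__(self) -> int:
        return len(self.channels)


@dataclass
class HyperplexStack:
    """Aligned concatenation of all imaging rounds, one frame of reference."""

    channels: list[ChannelImage]
    marker_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("stack must contain at least one channel")
        if not self.marker_names:
            self.marker_names = _disambiguate([c.channel_name for c in self.channels])
        if len(self.marker_names) != len(self.channels):
            raise ValueError("marker_names length must match channel count")
        if len(set(self.marker_names)) != len(self.marker_names):
            raise ValueError("marker_names must be unique")
        shapes = {c.shape for c in self.channels}
        if len(shapes) != 1:
            raise ValueError("channels differ in shape")

    @property
    def pixel_size(self) -> float:
        return self.channels[0].pixel_size

    @property
    def shape(self) -> tuple[int, int]:
        return self.channels[0].shape

    def __len__(self) -> int:
        return len(self.channels)

    def channel(self, marker: str) -> ChannelImage:
        """Look a channel up by its (disambiguated) marker name."""
        try:
            idx = self.marker_names.index(marker)
        except ValueError:
            raise KeyError(f"no channel named {marker!r}") from None
        return self.channels[idx]

    def asarray(self) -> np.ndarray:
        """Materialise the full (C, Y, X) array. Use sparingly on large stacks."""
        return np.stack([c.pixels for c in self.channels])


def _disambiguate(names: list[str]) -> list[str]:
    """Append ``_r<round>`` (then a counter) to repeated channel names."""
    out: list[str] = []
    seen: dict[str, int] = {}
    for name in names:
        if name not in seen:
            seen[name] = 1
            out.append(name)
        else:
            seen[name] += 1
            candidate = f"{name}_{seen[name]}"
            while candidate in seen:
                seen[name] += 1
                candidate = f"{name}_{seen[name]}"
            seen[candidate] = 1
            out.append(candidate)
    return out
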