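"""Reading, streaming, and writing multi-channel whole-slide TIFFs.

OME-TIFF is the preferred on-disk format: channel names travel in the OME
XML, pixel size in PhysicalSizeX/Y, pixels are 16-bit unsigned, and channels
are stored one per IFD so that streaming a single channel never touches the
rest of the stack. Plain multi-page TIFF is also read (names supplied by the
caller). Pyramids are dyadic: level k has shape ceil(shape / 2**k).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile
import zarr

from hifi.stack import ChannelImage, HyperplexStack, RoundStack

__all__ = ["read_round", "stream_channel", "write_hyperplex", "read_hyperplex"]

_DESC_KEY = "hifi_metadata"


def _parse_metadata(tif: tifffile.TiffFile) -> tuple[list[str] | None, float | None]:
    """Extract (channel names, pixel size µm) from OME XML or a JSON sidecar tag."""
    names: list[str] | None = None
    pixel_size: float | None = None
    if tif.is_ome and tif.ome_metadata:
        meta = tifffile.xml2dict(tif.ome_metadata)
        image = meta.get("OME", {}).get("Image")
        if isinstance(image, list):
            image = image[0]
        pixels = (image or {}).get("Pixels", {})
        sx = pixels.get("PhysicalSizeX")
        sy = pixels.get("PhysicalSizeY", sx)
        if sx is not None:
            if sy is not None and not np.isclose(float(sx), float(sy)):
                raise ValueError(
                    f"anisotropic pixels not supported: {sx} x {sy} µm"
                )
            pixel_size = float(sx)
        chans = pixels.get("Channel")
        if chans is not None:
            if isinstance(chans, dict):
                chans = [chans]
            parsed = [c.get("Name") for c in chans]
            if all(n is not None for n in parsed):
                names = [str(n) for n in parsed]
    else:
        desc = tif.pages[0].description
        if desc:
            try:
                payload = json.loads(desc)
            except (json.JSONDecodeError, TypeError):
                payload = None
            if isinstance(payload, dict) and _DESC_KEY in payload:
                payload = payload[_DESC_KEY]
                names = payload.get("channel_names")
                pixel_size = payload.get("pixel_size_um")
    return names, pixel_size


def read_round(
    path: str | Path,
    channel_names: list[str] | None = None,
    pixel_size_override: float | None = None,
    dapi_name: str = "DAPI",
    round_index: int = 0,
) -> RoundStack:
    """Read one imaging round from a (OME-)TIFF into memory.

    Metadata is resolved from file tags; explicit arguments win on conflict.

    Parameters
    ----------
    path : path to a multi-channel TIFF (channels along the first axis).
    channel_names : names for each channel; required when the file has none.
    pixel_size_override : µm per pixel, overriding any file tag.
    dapi_name : channel name identifying the nuclear reference channel.
    round_index : zero-based round index recorded on each channel.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        file_names, file_pixel_size = _parse_metadata(tif)
        data = tif.series[0].asarray()
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ValueError(f"expected a (C, Y, X) image, got shape {data.shape}")

    n_channels = data.shape[0]
    names = channel_names if channel_names is not None else file_names
    if names is None:
        raise ValueError("file carries no channel names; pass channel_names")
    if len(names) != n_channels:
        raise ValueError(
            f"channel-count mismatch: file has {n_channels} channels, "
            f"{len(names)} names supplied"
        )
    pixel_size = pixel_size_override if pixel_size_override is not None else file_pixel_size
    if pixel_size is None:
        raise ValueError("file carries no pixel size; pass pixel_size_override")

    channels = [
        ChannelImage(data[i], pixel_size, names[i], round_index)
        for i in range(n_channels)
    ]
    dapi_hits = [i for i, n in enumerate(names) if n == dapi_name]
    dapi_index = dapi_hits[0] if dapi_hits else 0
    return RoundStack(channels=channels, dapi_index=dapi_index)


def stream_channel(path: str | Path, channel_index: int) -> ChannelImage:
    """Read a single channel, keeping only that channel resident in memory.

    The peak working set is one full-resolution channel plus constant
    overhead — never the whole stack — because each channel occupies its own
    IFD and is decoded independently.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        names, pixel_size = _parse_metadata(tif)
        pages = tif.series[0].pages
        n = len(pages)
        if not 0 <= channel_index < n:
            raise IndexError(f"channel index {channel_index} out of range [0, {n})")
        try:
            # decode chunk rows through the zarr store: peak allocation is the
            # output channel plus one row of tiles, independent of stack depth
            with tif.aszarr(series=0, level=0) as store:
                z = zarr.open(store, mode="r")
                pixels = z[channel_index]
        except Exception:  # pragma: no cover - fallback for exotic layouts
            pixels = pages[channel_index].asarray()
    name = names[channel_index] if names else ""
    return ChannelImage(pixels, pixel_size or 1.0, name)


def _downsample(arr: np.ndarray) -> np.ndarray:
    """2x2 block-mean downsample with edge padding to ceil(shape/2)."""
    r, c = arr.shape
    pr, pc = r % 2, c % 2
    if pr or pc:
        arr = np.pad(arr, ((0, pr), (0, pc)), mode="edge")
    a = arr.astype(np.float64)
    out = (a[0::2, 0::2] + a[1::2, 0::2] + a[0::2, 1::2] + a[1::2, 1::2]) / 4.0
    return np.round(out).astype(arr.dtype)


def write_hyperplex(
    stack: HyperplexStack,
    path: str | Path,
    pyramid_levels: int = 1,
    tile_size: int = 256,
    compression: str = "zlib",
) -> Path:
    """Write an aligned stack as a tiled, pyramidal OME-TIFF.

    Level 0 is lossless; levels 1..k-1 are 2x block-mean downsamples.
    Pixel size and marker names are written into the OME metadata and are
    recoverable by :func:`read_round` / :func:`read_hyperplex`.
    """
    if pyramid_levels < 1:
        raise ValueError("pyramid_levels must be >= 1")
    if tile_size < 16 or tile_size % 16:
        raise ValueError("tile_size must be a positive multiple of 16")
    path = Path(path)
    data = stack.asarray().astype(np.uint16)
    px = stack.pixel_size
    metadata = {
        "axes": "CYX",
        "Channel": {"Name": list(stack.marker_names)},
        "PhysicalSizeX": px,
        "PhysicalSizeXUnit": "µm",
        "PhysicalSizeY": px,
        "PhysicalSizeYUnit": "µm",
    }
    opts = dict(tile=(tile_size, tile_size), compression=compression)
    with tifffile.TiffWriter(path, ome=True, bigtiff=data.nbytes > 2**31) as tw:
        tw.write(data, subifds=pyramid_levels - 1, metadata=metadata, **opts)
        level = data
        for _ in range(pyramid_levels - 1):
            level = np.stack([_downsample(ch) for ch in level])
            tw.write(level, subfiletype=1, **opts)
    return path


def read_hyperplex(path: str | Path, level: int = 0) -> HyperplexStack:
    """Read a pyramidal hyperplex OME-TIFF back at the requested level."""
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        names, pixel_size = _parse_metadata(tif)
        series = tif.series[0]
        levels = series.levels if hasattr(series, "levels") else [series]
        if not 0 <= level < len(levels):
            raise IndexError(f"pyramid level {level} out of range [0, {len(levels)})")
        data = levels[level].asarray()
    if data.ndim == 2:
        data = data[None]
    if pixel_size is None:
        pixel_size = 1.0
    eff_px = pixel_size * (2**level)
    if names is None:
        names = [f"channel_{i}" for i in range(data.shape[0])]
    channels = [ChannelImage(data[i], eff_px, names[i]) for i in range(data.shape[0])]
    return HyperplexStack(channels=channels, marker_names=list(names))


def write_round(
    rnd: RoundStack, path: str | Path, tile_size: int = 256, compression: str = "zlib"
) -> Path:
    """Write one round as a tiled OME-TIFF (single pyramid level)."""
    stack = HyperplexStack(channels=rnd.channels, marker_names=rnd.channel_names)
    return write_hyperplex(stack, path, pyramid_levels=1, tile_size=tile_size, compression=compression)
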