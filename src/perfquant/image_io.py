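"""Image and table I/O carrying physical pixel-size metadata.

Microscopy images enter the pipeline as :class:`PixelGrid` objects: a
single-channel 2D intensity array plus the physical edge length of one
pixel (``pd``, in µm).  Multi-channel acquisitions (e.g. the green/red
live/dead pair, or DAPI + phalloidin) are held in a
:class:`MultiChannelImage`, a named mapping of channels that share shape
and pixel size.

Pixel size is never read from file metadata; it must be supplied by the
caller and defaults to 1.0 µm/px with a logged warning, since acquisition
scale is an instrument property that cannot be trusted to survive format
conversions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "PixelGrid",
    "MultiChannelImage",
    "load_image",
    "save_image",
    "write_table",
    "read_table",
]

_TIFF_SUFFIXES = {".tif", ".tiff"}


class FormatError(ValueError):
    """Raised for unsupported image formats or bit depths."""


@dataclass(frozen=True)
class PixelGrid:
    """A single-channel 2D intensity image with physical pixel size.

    Parameters
    ----------
    values : ndarray
        2D array of non-negative integer intensities (uint8 or uint16).
    bit_depth : int
        8 or 16; intensities must lie in ``[0, 2**bit_depth - 1]``.
    pd : float
        Pixel dimension: physical edge length of one pixel in µm (> 0).
    """

    values: np.ndarray
    bit_depth: int = 8
    pd: float = 1.0

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2 or v.shape[0] < 1 or v.shape[1] < 1:
            raise ValueError(f"values must be a non-empty 2D array, got shape {v.shape}")
        if self.bit_depth not in (8, 16):
            raise FormatError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if not (self.pd > 0):
            raise ValueError(f"pixel size pd must be > 0, got {self.pd}")
        vmax = 2**self.bit_depth - 1
        if v.min() < 0 or v.max() > vmax:
            raise ValueError(f"intensities outside [0, {vmax}]")
        object.__setattr__(self, "values", v)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @classmethod
    def from_array(cls, arr: np.ndarray, pd: float = 1.0) -> "PixelGrid":
        """Wrap an integer array, inferring bit depth from dtype."""
        arr = np.asarray(arr)
        if arr.dtype == np.uint8:
            depth = 8
        elif arr.dtype == np.uint16:
            depth = 16
        else:
            raise FormatError(f"unsupported dtype {arr.dtype}; expected uint8 or uint16")
        return cls(values=arr, bit_depth=depth, pd=pd)


@dataclass(frozen=True)
class MultiChannelImage:
    """Named channels sharing shape and pixel size."""

    channels: Mapping[str, PixelGrid]

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("at least one channel is required")
        shapes = {g.shape for g in self.channels.values()}
        pds = {g.pd for g in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channels differ in shape: {shapes}")
        if len(pds) != 1:
            raise ValueError(f"channels differ in pixel size: {pds}")
        object.__setattr__(self, "channels", dict(self.channels))

    def __getitem__(self, name: str) -> PixelGrid:
        return self.channels[name]

    def __contains__(self, name: str) -> bool:
        return name in self.channels

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def pd(self) -> float:
        return next(iter(self.channels.values())).pd

    @property
    def names(self) -> list[str]:
        return list(self.channels)

    def rename(self, aliases: Mapping[str, str]) -> "MultiChannelImage":
        """Return a copy with channels renamed, e.g. ``{"green": "live"}``."""
        return MultiChannelImage(
            {aliases.get(k, k): v for k, v in self.channels.items()}
        )

    def stack(self) -> np.ndarray:
        """Stack channels along the last axis, in insertion order."""
        return np.stack([g.values for g in self.channels.values()], axis=-1)


def _infer_depth(arr: np.ndarray) -> int:
    if arr.dtype == np.uint8:
        return 8
    if arr.dtype == np.uint16:
        return 16
    raise FormatError(f"unsupported bit depth: dtype {arr.dtype} (expected uint8/uint16)")


def load_image(path: str | Path, pd: float | None = None) -> MultiChannelImage:
    """Read a TIFF or PNG image into a :class:`MultiChannelImage`.

    Grayscale input yields one channel named ``"gray"``; RGB(A) input is
    split into ``red``/``green``/``blue`` (alpha is discarded).  ``pd`` is
    attached to every channel; when omitted it defaults to 1.0 µm/px and a
    warning is logged, because physical areas are meaningless without it.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if pd is None:
        pd = 1.0
        logger.warning(
            "no pixel size supplied for %s; defaulting to 1.0 um/px "
            "(physical areas will be in pixel units)",
            path,
        )
    if pd <= 0:
        raise ValueError(f"pixel size pd must be > 0, got {pd}")

    if path.suffix.lower() in _TIFF_SUFFIXES:
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    arr = np.asarray(arr)
    depth = _infer_depth(arr)

    if arr.ndim == 2:
        grids = {"gray": PixelGrid(arr, depth, pd)}
    elif arr.ndim == 3 and arr.shape[-1] in (3, 4):
        if arr.shape[-1] == 4:
            logger.info("discarding alpha channel of %s", path)
        grids = {
            name: PixelGrid(arr[..., i], depth, pd)
            for i, name in enumerate(("red", "green", "blue"))
        }
    else:
        raise FormatError(f"unsupported image layout with shape {arr.shape}")
    return MultiChannelImage(grids)


def save_image(image: MultiChannelImage | PixelGrid | np.ndarray, path: str | Path) -> None:
    """Write a grid (or a 1/3-channel image) as single-plane TIFF or PNG."""
    path = Path(path)
    if isinstance(image, MultiChannelImage):
        if len(image.channels) == 1:
            arr = next(iter(image.channels.values())).values
        elif len(image.channels) == 3:
            arr = image.stack()
        else:
            raise FormatError(
                f"can only save 1- or 3-channel images, got {len(image.channels)}"
            )
    elif isinstance(image, PixelGrid):
        arr = image.values
    else:
        arr = np.asarray(image)
        _infer_depth(arr)
    if path.suffix.lower() in _TIFF_SUFFIXES:
        tifffile.imwrite(path, arr)
    else:
        iio.imwrite(path, arr)


def write_table(records: Sequence | pd.DataFrame, path: str | Path) -> None:
    """Write result rows as a headed CSV with >= 6 significant digits.

    ``records`` may be a DataFrame, a sequence of dataclasses, dicts or
    namedtuples sharing a common field set.  An empty sequence writes a
    header-only file when fields can be inferred, otherwise an empty file.
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        rows = []
        for r in records:
            if hasattr(r, "_asdict"):
                rows.append(r._asdict())
            elif hasattr(r, "__dataclass_fields__"):
                rows.append({k: getattr(r, k) for k in r.__dataclass_fields__})
            elif isinstance(r, Mapping):
                rows.append(dict(r))
            else:
                raise TypeError(f"cannot turn {type(r).__name__} into a table row")
        df = pd.DataFrame(rows)
    df.to_csv(path, index=False, float_format="%.8g")


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a CSV/TSV table, sniffing the delimiter."""
    return pd.read_csv(path, sep=None, engine="python")
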