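"""Frame and table I/O.

Frames travel as 8- or 16-bit grayscale TIFF (single- or multi-page, via
tifffile) or PNG (via imageio); the physical pixel pitch is not stored in
these formats and is carried alongside as an explicit argument or a sidecar.
Color images and unsupported bit depths raise :class:`FormatError` naming
the offending file.  Tables are plain CSV with a fixed column order.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .frame import FrameImage

__all__ = [
    "FormatError",
    "read_frame",
    "write_frame",
    "read_frame_series",
    "write_frame_series",
    "read_table",
    "write_table",
]


class FormatError(ValueError):
    """Unsupported image format, bit depth, or color layout."""


_OK_DTYPES = (np.uint8, np.uint16)


def _check_gray(arr: np.ndarray, path: str) -> np.ndarray:
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):
        raise FormatError(f"{path}: color images are not supported (grayscale only)")
    if arr.ndim != 2:
        raise FormatError(f"{path}: expected a single 2-D grayscale image, got shape {arr.shape}")
    if arr.dtype not in _OK_DTYPES:
        raise FormatError(f"{path}: unsupported dtype {arr.dtype} (8/16-bit grayscale only)")
    return arr


def read_frame(path: str | Path, pitch_um: float) -> FrameImage:
    """Read one grayscale frame; ``pitch_um`` supplies the physical scale."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
        if arr.ndim == 3 and arr.shape[-1] not in (3, 4):
            raise FormatError(f"{path}: multi-page TIFF; use read_frame_series")
    else:
        arr = iio.imread(path)
    return FrameImage(_check_gray(np.asarray(arr), str(path)), pitch_um)


def write_frame(path: str | Path, frame: FrameImage) -> None:
    """Write as 16-bit grayscale (TIFF or PNG by extension).

    Intensities are rounded to the nearest integer and clipped to the uint16
    range; integer-valued data round-trips exactly.
    """
    path = Path(path)
    arr = np.clip(np.round(frame.pixels), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr, photometric='minisblack')
    else:
        iio.imwrite(path, arr)


def read_frame_series(path: str | Path, pitch_um: float,
                      times_s: list[float] | None = None
                      ) -> list[tuple[float, FrameImage]]:
    """Read a multi-page TIFF as a (time, frame) series.

    ``times_s`` (one entry per page) defaults to the page index.
    """
    path = Path(path)
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise FormatError(f"{path}: expected a stack of 2-D grayscale pages")
    if times_s is None:
        times_s = list(range(arr.shape[0]))
    if len(times_s) != arr.shape[0]:
        raise FormatError(f"{path}: {arr.shape[0]} pages but {len(times_s)} times")
    return [(float(t), FrameImage(_check_gray(a, str(path)), pitch_um))
            for t, a in zip(times_s, arr)]


def write_frame_series(path: str | Path, series: list[tuple[float, FrameImage]]) -> None:
    """Write a (time, frame) series as multi-page 16-bit TIFF + times CSV sidecar."""
    path = Path(path)
    stack = np.stack([
        np.clip(np.round(f.pixels), 0, np.iinfo(np.uint16).max).astype(np.uint16)
        for _, f in series])
    tifffile.imwrite(path, stack, photometric='minisblack')
    pd.DataFrame({"page": range(len(series)), "time_s": [t for t, _ in series]}) \
        .to_csv(path.with_suffix(".times.csv"), index=False)


def write_table(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
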