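"""Raster image reading/writing (PNM, PNG, TIFF, BMP) and the ratio metric.

PNM (P2/P3/P5/P6) is parsed and written directly: comments and arbitrary
whitespace are accepted in headers, and 16-bit binary samples are
big-endian per the netpbm standard.  PNG and BMP go through Pillow, TIFF
through tifffile.  Compression ratio is defined as the on-disk size of the
original container divided by the compressed size, so ratios below 1 are
legal when the source container is itself compressed.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

from .dt_core import PixelGrid

__all__ = [
    "ImageRecord",
    "UnsupportedFormatError",
    "read_image",
    "write_image",
    "compression_ratio",
]

_PNM_EXTS = {".pgm", ".ppm", ".pnm"}
_FORMATS = {"pnm", "png", "tiff", "bmp"}


class UnsupportedFormatError(ValueError):
    """File format or depth/format combination not supported."""


@dataclass(frozen=True)
class ImageRecord:
    """A decoded image together with its on-disk container provenance."""

    path: Path
    format: str
    byte_size: int
    grid: PixelGrid


def _format_for(path: Path, fmt: str | None = None) -> str:
    if fmt is not None:
        fmt = fmt.lower()
        if fmt in ("tif",):
            fmt = "tiff"
        if fmt in ("pgm", "ppm"):
            fmt = "pnm"
        if fmt not in _FORMATS:
            raise UnsupportedFormatError(f"unsupported format {fmt!r}")
        return fmt
    ext = path.suffix.lower()
    if ext in _PNM_EXTS:
        return "pnm"
    if ext == ".png":
        return "png"
    if ext in (".tif", ".tiff"):
        return "tiff"
    if ext == ".bmp":
        return "bmp"
    raise UnsupportedFormatError(f"unsupported file extension {ext!r} ({path})")


# ---------------------------------------------------------------- PNM ----

def _pnm_tokens(data: bytes):
    """Yield whitespace-separated header tokens, skipping '#' comments.

    Also yields the byte offset just past each token so binary payload
    parsing knows where the header ended.
    """
    i = 0
    n = len(data)
    while i < n:
        c = data[i : i + 1]
        if c in b" \t\r\n\x0b\x0c":
            i += 1
        elif c == b"#":
            while i < n and data[i : i + 1] != b"\n":
                i += 1
        else:
            j = i
            while j < n and data[j : j + 1] not in b" \t\r\n\x0b\x0c#":
                j += 1
            yield data[i:j], j
            i = j


def _read_pnm(data: bytes, path: Path) -> PixelGrid:
    tokens = _pnm_tokens(data)
    try:
        magic, _ = next(tokens)
    except StopIteration:
        raise UnsupportedFormatError(f"empty PNM file {path}") from None
    if magic not in (b"P2", b"P3", b"P5", b"P6"):
        raise UnsupportedFormatError(f"unsupported PNM magic {magic!r} ({path})")
    ascii_mode = magic in (b"P2", b"P3")
    channels = 3 if magic in (b"P3", b"P6") else 1
    try:
        width = int(next(tokens)[0])
        height = int(next(tokens)[0])
        maxval, end = next(tokens)
        maxval = int(maxval)
    except (StopIteration, ValueError) as exc:
        raise ValueError(f"malformed PNM header in {path}: {exc}") from exc
    if not 0 < maxval < 65536:
        raise ValueError(f"PNM maxval {maxval} out of range in {path}")
    bit_depth = 8 if maxval <= 255 else 16
    count = width * height * channels
    if ascii_mode:
        values = []
        for tok, _ in tokens:
            values.append(int(tok))
            if len(values) == count:
                break
        if len(values) != count:
            raise ValueError(
                f"PNM payload short: {len(values)} of {count} samples in {path}"
            )
        arr = np.array(values, dtype=np.int64)
    else:
        # Binary payload starts after exactly one whitespace byte past maxval.
        start = end + 1
        dtype = np.dtype(">u2") if bit_depth == 16 else np.dtype("u1")
        need = count * dtype.itemsize
        raw = data[start : start + need]
        if len(raw) < need:
            raise ValueError(
                f"PNM payload short: {len(raw)} of {need} bytes in {path}"
            )
        arr = np.frombuffer(raw, dtype=dtype).astype(np.int64)
    if arr.size and arr.max() > maxval:
        raise ValueError(f"PNM sample exceeds maxval {maxval} in {path}")
    samples = arr.reshape(height, width, channels)
    return PixelGrid(samples=samples, bit_depth=bit_depth)


def _write_pnm(grid: PixelGrid, path: Path) -> None:
    if grid.channels == 1:
        magic = b"P5"
    else:
        magic = b"P6"
    header = b"%s\n%d %d\n%d\n" % (magic, grid.width, grid.height, grid.max_value)
    if grid.bit_depth == 16:
        payload = grid.samples.astype(">u2").tobytes()
    else:
        payload = grid.samples.astype("u1").tobytes()
    path.write_bytes(header + payload)


# ----------------------------------------------------- PNG / BMP / TIFF ----

def _grid_from_array(arr: np.ndarray, path: Path) -> PixelGrid:
    if arr.ndim == 2:
        arr = arr[:, :, np.newaxis]
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha if fully opaque
        raise UnsupportedFormatError(f"alpha channel not supported ({path})")
    bit_depth = 16 if arr.dtype.itemsize >= 2 else 8
    return PixelGrid(samples=arr.astype(np.int64), bit_depth=bit_depth)


def _read_pil(path: Path) -> PixelGrid:
    with Image.open(path) as img:
        if img.mode == "P":
            img = img.convert("RGB")
        arr = np.asarray(img)
    if arr.dtype == np.int32:  # Pillow mode "I"
        arr = arr.astype(np.uint16)
    return _grid_from_array(arr, path)


def read_image(path: str | os.PathLike) -> ImageRecord:
    """Read a raster file into a :class:`PixelGrid`, keeping its byte size."""
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(path)
    fmt = _format_for(path)
    byte_size = path.stat().st_size
    if fmt == "pnm":
        grid = _read_pnm(path.read_bytes(), path)
    elif fmt == "tiff":
        grid = _grid_from_array(tifffile.imread(path), path)
    else:
        grid = _read_pil(path)
    return ImageRecord(path=path, format=fmt, byte_size=byte_size, grid=grid)


def write_image(
    grid: PixelGrid, path: str | os.PathLike, format: str | None = None
) -> int:
    """Write ``grid`` to ``path``; returns the container size in bytes."""
    path = Path(path)
    fmt = _format_for(path, format)
    if fmt == "pnm":
        _write_pnm(grid, path)
    elif fmt == "tiff":
        arr = grid.samples if grid.channels == 3 else grid.samples[:, :, 0]
        tifffile.imwrite(path, arr, compression="deflate")
    elif fmt == "png":
        if grid.bit_depth == 16 and grid.channels == 3:
            raise UnsupportedFormatError(
                "16-bit RGB PNG writing not supported; use PNM or TIFF"
            )
        if grid.bit_depth == 16:
            img = Image.fromarray(grid.samples[:, :, 0].astype(np.uint16))
        elif grid.channels == 1:
            img = Image.fromarray(grid.samples[:, :, 0].astype(np.uint8), mode="L")
        else:
            img = Image.fromarray(grid.samples.astype(np.uint8), mode="RGB")
        img.save(path, format="PNG")
    elif fmt == "bmp":
        if grid.bit_depth == 16:
            raise UnsupportedFormatError("BMP does not support 16-bit samples")
        if grid.channels == 1:
            img = Image.fromarray(grid.samples[:, :, 0].astype(np.uint8), mode="L")
        else:
            img = Image.fromarray(grid.samples.astype(np.uint8), mode="RGB")
        img.save(path, format="BMP")
    return path.stat().st_size


def compression_ratio(original_bytes: int, compressed_bytes: int) -> float:
    """Original container size divided by compressed size (may be < 1)."""
    if original_bytes <= 0 or compressed_bytes <= 0:
        raise ValueError(
            f"byte counts must be positive, got {original_bytes} and "
            f"{compressed_bytes}"
        )
    return original_bytes / compressed_bytes
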