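"""Integer difference transform: 1D and single-level 2D analysis/synthesis.

The transform splits a signal into the samples at even indices (kept
verbatim) and, at each odd index, the floored average of its two even
neighbors minus the sample itself.  Because the synthesis step recomputes
the identical floored average from the identical retained samples, the
round trip is bit-exact for any integer input.

In two dimensions the same three-tap filter (1/2, -1, 1/2) is applied
along rows, columns and the main diagonal, producing four quadrants:

    +----+----+       WS  retained pixels f(2m, 2n)
    | WS | WH |       WH  horizontal details (even row, odd column)
    +----+----+       WV  vertical details  (odd row, even column)
    | WV | WD |       WD  diagonal details  (odd row, odd column)
    +----+----+

WS is ceil(H/2) x ceil(W/2); the detail quadrants take the floor halves,
so arbitrary (odd or even) dimensions are supported.  Out-of-range even
neighbors at the borders are replicated (clamped indexing), identically
in analysis and synthesis.

All detail coefficients of an N-bit image lie in [-(2^N - 1), 2^N - 1],
strictly inside the interval [-2^N, 2^N].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "FILTER_TAPS",
    "PixelGrid",
    "CoeffGrid",
    "forward_1d",
    "inverse_1d",
    "forward_plane",
    "inverse_plane",
    "forward_2d",
    "inverse_2d",
]

#: Three-tap detail filter h(-1)=1/2, h(0)=-1, h(1)=1/2 (zero-sum, symmetric).
FILTER_TAPS = (0.5, -1.0, 0.5)


@dataclass(frozen=True)
class PixelGrid:
    """Integer raster of shape (height, width, channels) with a declared depth.

    Samples are stored as an unsigned numpy array; every value must lie in
    ``[0, 2**bit_depth - 1]``.  Both spatial dimensions must be >= 3 so that
    every odd position has at least one even neighbor on some side.
    """

    samples: np.ndarray
    bit_depth: int

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples)
        if arr.ndim == 2:
            arr = arr[:, :, np.newaxis]
        if arr.ndim != 3:
            raise ValueError(f"samples must be 2-D or 3-D, got ndim={arr.ndim}")
        if not np.issubdtype(arr.dtype, np.integer):
            raise TypeError(f"samples must be integers, got dtype {arr.dtype}")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if arr.shape[2] not in (1, 3):
            raise ValueError(f"channels must be 1 or 3, got {arr.shape[2]}")
        if arr.shape[0] < 3 or arr.shape[1] < 3:
            raise ValueError(
                f"image must be at least 3x3, got {arr.shape[0]}x{arr.shape[1]}"
            )
        maxval = (1 << self.bit_depth) - 1
        if arr.size and (arr.min() < 0 or arr.max() > maxval):
            raise ValueError(f"sample values outside [0, {maxval}]")
        dtype = np.uint8 if self.bit_depth == 8 else np.uint16
        object.__setattr__(self, "samples", np.ascontiguousarray(arr, dtype=dtype))

    @property
    def height(self) -> int:
        return self.samples.shape[0]

    @property
    def width(self) -> int:
        return self.samples.shape[1]

    @property
    def channels(self) -> int:
        return self.samples.shape[2]

    @property
    def max_value(self) -> int:
        return (1 << self.bit_depth) - 1

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PixelGrid):
            return NotImplemented
        return self.bit_depth == other.bit_depth and np.array_equal(
            self.samples, other.samples
        )


@dataclass(frozen=True)
class CoeffGrid:
    """Signed transform coefficients in the packed quadrant layout.

    Shape and sample count mirror the source :class:`PixelGrid`; the
    transform is a permutation plus a reversible integer map, so there is
    no expansion.  ``values`` is an int64 array of shape (H, W, C).
    """

    values: np.ndarray
    bit_depth: int

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if arr.ndim == 2:
            arr = arr[:, :, np.newaxis]
        if arr.ndim != 3:
            raise ValueError(f"values must be 2-D or 3-D, got ndim={arr.ndim}")
        if not np.issubdtype(arr.dtype, np.integer):
            raise TypeError(f"values must be integers, got dtype {arr.dtype}")
        object.__setattr__(self, "values", np.ascontiguousarray(arr, dtype=np.int64))

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]

    @property
    def channels(self) -> int:
        return self.values.shape[2]


def _validate_sequence(x: np.ndarray, bit_depth: int | None) -> np.ndarray:
    if x.ndim != 1:
        raise ValueError("expected a 1-D sequence")
    if not np.issubdtype(x.dtype, np.integer):
        raise TypeError(f"sequence must hold integers, got dtype {x.dtype}")
    if x.shape[0] < 3:
        raise ValueError(f"sequence length must be >= 3, got {x.shape[0]}")
    if x.size and x.min() < 0:
        raise ValueError("sample values must be non-negative")
    if bit_depth is not None:
        maxval = (1 << bit_depth) - 1
        if x.size and x.max() > maxval:
            raise ValueError(f"sample values outside [0, {maxval}]")
    return x.astype(np.int64)


def forward_1d(
    seq, bit_depth: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Split ``seq`` into retained even samples and odd-position details.

    ``details[j] = floor((left + right) / 2) - seq[2j+1]`` where *left* and
    *right* are the even-index neighbors of position ``2j+1`` (the right
    neighbor is clamped to the last even index when the sequence ends on
    the odd position).  ``len(evens) + len(details) == len(seq)``.
    """
    x = _validate_sequence(np.asarray(seq), bit_depth)
    L = x.shape[0]
    evens = x[0::2].copy()
    odd = np.arange(1, L, 2)
    last_even = 2 * ((L - 1) // 2)
    left = x[odd - 1]
    right = x[np.minimum(odd + 1, last_even)]
    details = ((left + right) >> 1) - x[odd]
    return evens, details


def inverse_1d(evens, details, length: int) -> np.ndarray:
    """Exact inverse of :func:`forward_1d` for a sequence of ``length``."""
    e = np.asarray(evens, dtype=np.int64)
    d = np.asarray(details, dtype=np.int64)
    if length < 3:
        raise ValueError(f"sequence length must be >= 3, got {length}")
    if e.shape[0] != (length + 1) // 2 or d.shape[0] != length // 2:
        raise ValueError(
            f"inconsistent lengths: got {e.shape[0]} evens and {d.shape[0]} "
            f"details for L={length}"
        )
    out = np.empty(length, dtype=np.int64)
    out[0::2] = e
    j = np.arange(length // 2)
    left = e[j]
    right = e[np.minimum(j + 1, e.shape[0] - 1)]
    out[1::2] = ((left + right) >> 1) - d
    return out


def _quadrant_dims(height: int, width: int) -> tuple[int, int, int, int]:
    """(ceil(H/2), ceil(W/2), floor(H/2), floor(W/2))."""
    return (height + 1) // 2, (width + 1) // 2, height // 2, width // 2


def forward_plane(plane: np.ndarray) -> np.ndarray:
    """Single-level 2D transform of one channel plane (2-D int array).

    Returns an int64 array of the same shape with the quadrants packed
    WS | WH over WV | WD.
    """
    f = np.asarray(plane)
    if f.ndim != 2:
        raise ValueError("plane must be 2-D")
    H, W = f.shape
    if H < 3 or W < 3:
        raise ValueError(f"plane must be at least 3x3, got {H}x{W}")
    f = f.astype(np.int64)
    hs, ws, hd, wd = _quadrant_dims(H, W)
    last_er = 2 * ((H - 1) // 2)  # last even row
    last_ec = 2 * ((W - 1) // 2)  # last even column
    rows = 2 * np.arange(hd)  # even row above each odd row
    cols = 2 * np.arange(wd)  # even column left of each odd column
    rows_below = np.minimum(rows + 2, last_er)
    cols_right = np.minimum(cols + 2, last_ec)

    out = np.empty((H, W), dtype=np.int64)
    even_rows = f[0::2]
    out[:hs, :ws] = even_rows[:, 0::2]  # WS
    out[:hs, ws:] = (
        (even_rows[:, cols] + even_rows[:, cols_right]) >> 1
    ) - even_rows[:, 1::2]  # WH
    out[hs:, :ws] = (
        (f[rows][:, 0::2] + f[rows_below][:, 0::2]) >> 1
    ) - f[1::2, 0::2]  # WV
    out[hs:, ws:] = (
        (f[np.ix_(rows, cols)] + f[np.ix_(rows_below, cols_right)]) >> 1
    ) - f[1::2, 1::2]  # WD
    return out


_PASSES = ("H", "V", "D")


def inverse_plane(
    coeffs: np.ndarray,
    height: int,
    width: int,
    pass_order: tuple[str, str, str] = _PASSES,
) -> np.ndarray:
    """Single-level inverse of :func:`forward_plane`.

    Each reconstruction pass depends only on the retained WS samples, so
    ``pass_order`` (any permutation of ``("H", "V", "D")``) cannot change
    the result; it is exposed to let tests assert exactly that.
    """
    c = np.asarray(coeffs)
    if c.ndim != 2 or c.shape != (height, width):
        raise ValueError(
            f"coefficient plane shape {c.shape} does not match {height}x{width}"
        )
    if sorted(pass_order) != sorted(_PASSES):
        raise ValueError(f"pass_order must permute {_PASSES}, got {pass_order}")
    c = c.astype(np.int64)
    hs, ws, hd, wd = _quadrant_dims(height, width)
    WS = c[:hs, :ws]
    WH = c[:hs, ws:]
    WV = c[hs:, :ws]
    WD = c[hs:, ws:]

    out = np.empty((height, width), dtype=np.int64)
    out[0::2, 0::2] = WS
    rows = np.arange(hd)
    cols = np.arange(wd)
    rows_below = np.minimum(rows + 1, hs - 1)
    cols_right = np.minimum(cols + 1, ws - 1)
    for p in pass_order:
        if p == "H":
            out[0::2, 1::2] = ((WS[:, cols] + WS[:, cols_right]) >> 1) - WH
        elif p == "V":
            out[1::2, 0::2] = ((WS[rows] + WS[rows_below]) >> 1) - WV
        else:
            out[1::2, 1::2] = (
                (WS[np.ix_(rows, cols)] + WS[np.ix_(rows_below, cols_right)]) >> 1
            ) - WD
    return out


def forward_2d(grid: PixelGrid) -> CoeffGrid:
    """Apply the single-level 2D transform to every channel independently."""
    values = np.empty(grid.samples.shape, dtype=np.int64)
    for ch in range(grid.channels):
        values[:, :, ch] = forward_plane(grid.samples[:, :, ch])
    return CoeffGrid(values=values, bit_depth=grid.bit_depth)


def inverse_2d(coeffs: CoeffGrid) -> PixelGrid:
    """Exact inverse of :func:`forward_2d`."""
    out = np.empty(coeffs.values.shape, dtype=np.int64)
    for ch in range(coeffs.channels):
        out[:, :, ch] = inverse_plane(
            coeffs.values[:, :, ch], coeffs.height, coeffs.width
        )
    return PixelGrid(samples=out, bit_depth=coeffs.bit_depth)
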