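"""Multiresolution decomposition by iterating the transform on WS.

Each level re-applies the single-level 2D transform to the retained-pixel
quadrant (WS) of the previous level, nesting quadrants in the top-left
corner.  Every level records its own (height, width), so the ceil/floor
quadrant splits of odd dimensions nest unambiguously and reconstruction
can walk the levels back in reverse order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dt_core import CoeffGrid, PixelGrid, forward_plane, inverse_plane

__all__ = ["PyramidSpec", "max_levels", "decompose", "reconstruct"]


def _halve(n: int) -> int:
    return (n + 1) // 2


def max_levels(height: int, width: int) -> int:
    """Number of decomposition levels applicable to a height x width plane.

    A level is applied while both dimensions are >= 3 and the plane has not
    shrunk to the 3x3 stopping size; WS keeps the ceil-half of each
    dimension.  max_levels(3, 3) == 0 by convention (the 3x3 base case is
    the stopping point, even though a lone single-level transform of a 3x3
    plane is itself well defined).
    """
    if height < 3 or width < 3:
        raise ValueError(f"dimensions must be >= 3, got {height}x{width}")
    h, w = height, width
    n = 0
    while h >= 3 and w >= 3 and (h, w) != (3, 3):
        h, w = _halve(h), _halve(w)
        n += 1
    return n


@dataclass(frozen=True)
class PyramidSpec:
    """Geometry of a multiresolution decomposition.

    ``level_dims[k]`` is the (height, width) of the plane transformed at
    level ``k`` (``level_dims[0]`` is the full image); the WS quadrant of
    level ``k`` has the ceil-half of those dimensions and is what level
    ``k + 1`` operates on.
    """

    height: int
    width: int
    channels: int
    bit_depth: int
    levels: int
    level_dims: tuple[tuple[int, int], ...] = field(init=False)

    def __post_init__(self) -> None:
        if self.levels < 1:
            raise ValueError(f"levels must be >= 1, got {self.levels}")
        dims = [(self.height, self.width)]
        for _ in range(self.levels - 1):
            h, w = dims[-1]
            dims.append((_halve(h), _halve(w)))
        for h, w in dims:
            if h < 3 or w < 3:
                raise ValueError(
                    f"level plane {h}x{w} is smaller than 3x3; "
                    f"{self.levels} levels do not fit {self.height}x{self.width}"
                )
        object.__setattr__(self, "level_dims", tuple(dims))

    @property
    def deepest_ws_dims(self) -> tuple[int, int]:
        h, w = self.level_dims[-1]
        return _halve(h), _halve(w)


def decompose(grid: PixelGrid, levels: int) -> tuple[CoeffGrid, PyramidSpec]:
    """Apply ``levels`` nested single-level transforms to every channel."""
    bound = max(1, max_levels(grid.height, grid.width))
    if not 1 <= levels <= bound:
        raise ValueError(
            f"levels must be in [1, {bound}] for a {grid.height}x{grid.width} "
            f"image, got {levels}"
        )
    spec = PyramidSpec(
        height=grid.height,
        width=grid.width,
        channels=grid.channels,
        bit_depth=grid.bit_depth,
        levels=levels,
    )
    values = grid.samples.astype(np.int64)
    out = np.empty_like(values)
    for ch in range(grid.channels):
        plane = values[:, :, ch].copy()
        for h, w in spec.level_dims:
            plane[:h, :w] = forward_plane(plane[:h, :w])
        out[:, :, ch] = plane
    return CoeffGrid(values=out, bit_depth=grid.bit_depth), spec


def reconstruct(coeffs: CoeffGrid, spec: PyramidSpec) -> PixelGrid:
    """Bit-exact inverse of :func:`decompose`."""
    if (coeffs.height, coeffs.width, coeffs.channels) != (
        spec.height,
        spec.width,
        spec.channels,
    ):
        raise ValueError(
            f"coefficient grid {coeffs.height}x{coeffs.width}x{coeffs.channels} "
            f"does not match spec {spec.height}x{spec.width}x{spec.channels}"
        )
    out = np.empty_like(coeffs.values)
    for ch in range(spec.channels):
        plane = coeffs.values[:, :, ch].copy()
        for h, w in reversed(spec.level_dims):
            plane[:h, :w] = inverse_plane(plane[:h, :w], h, w)
        out[:, :, ch] = plane
    return PixelGrid(samples=out, bit_depth=spec.bit_depth)
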