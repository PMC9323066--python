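# difftx

A bit-exact lossless image codec built on an integer *difference transform*:
the image is split into retained even-grid pixels and signed residuals
("neighbor-average minus sample") at odd positions, applied recursively to
the retained quadrant for a multiresolution decomposition, and the resulting
coefficients are entropy-coded with a static canonical Huffman code into a
self-contained `.tdc` container. Decompression reproduces every original
sample exactly.

Supported inputs: PGM/PPM (8/16-bit, ASCII and binary), PNG, TIFF, BMP;
grayscale and RGB; any width/height >= 3, odd or even.

## Layout

| module              | role                                                        |
| ------------------- | ----------------------------------------------------------- |
| `difftx.dt_core`    | 1D and single-level 2D transform and exact inverses         |
| `difftx.pyramid`    | multiresolution decomposition/reconstruction, level limits  |
| `difftx.codec`      | canonical Huffman coding and the `.tdc` container           |
| `difftx.imagio`     | raster readers/writers and the compression-ratio metric     |
| `difftx.bench_cli`  | CLI, synthetic fixture generator, benchmark tables          |

## CLI

```sh
difftx fixtures --out-dir fixtures --seed 1 --height 64 --width 64
difftx compress fixtures/blob_phantom_64x64_8bit_c1_s1.pgm -o img.tdc --levels max
difftx verify   fixtures/blob_phantom_64x64_8bit_c1_s1.pgm img.tdc   # PASS
difftx decompress img.tdc -o restored.pgm
difftx bench fixtures --levels max       # per-file ratios + min/mean/max
```

`--levels` selects the decomposition depth (`max`, the default, uses the
deepest legal decomposition). Compression ratio is the on-disk size of the
original container divided by the `.tdc` size, so ratios below 1 are
possible when the source container (PNG/TIFF) is already compressed.

## Library

```python
import numpy as np
from difftx import PixelGrid, compress_grid, decompress_grid

grid = PixelGrid(np.random.default_rng(0).integers(0, 256, (64, 64, 3)), bit_depth=8)
stream = compress_grid(grid, levels="max")
assert decompress_grid(stream) == grid
```

## `.tdc` container

Little-endian: magic `TDC1`, u8 version, u32 height, u32 width, u8 channels,
u8 bit depth, u8 levels, u32 codebook entry count, entries as
(i32 symbol, u8 code length), u64 payload bit count, then the payload bits
MSB-first, zero-padded to a byte boundary. Codes are canonical, rebuilt
from the (symbol, length) pairs on decode; one codebook is shared by all
channels and levels.
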