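"""Static canonical Huffman coding of transform coefficients and the
`.tdc` container format.

Container layout (all integers little-endian):

    magic "TDC1"            4 bytes
    version                 u8   (currently 1)
    height                  u32
    width                   u32
    channels                u8
    bit_depth               u8
    levels                  u8
    codebook entry count    u32
    entries                 (i32 symbol, u8 code length) each
    payload bit count       u64
    payload                 bits MSB-first, zero-padded to a byte boundary

One codebook is shared by all channels and levels: every coefficient
(unsigned retained pixels and signed details alike) is carried in a single
signed-integer alphabet.  Codes are canonical, so only (symbol, length)
pairs are stored and the decoder rebuilds the identical code assignment.
"""

from __future__ import annotations

import heapq
import struct
from dataclasses import dataclass

import numpy as np

from .dt_core import CoeffGrid, PixelGrid
from .pyramid import PyramidSpec, decompose, max_levels, reconstruct

__all__ = [
    "MAGIC",
    "VERSION",
    "FormatError",
    "CorruptionError",
    "HuffmanCodebook",
    "build_codebook",
    "encode",
    "decode",
    "compress_grid",
    "decompress_grid",
]

MAGIC = b"TDC1"
VERSION = 1

_HEADER = struct.Struct("<4sBIIBBBI")
_ENTRY = struct.Struct("<iB")
_BITCOUNT = struct.Struct("<Q")


class FormatError(ValueError):
    """Stream does not start with a valid header."""


class CorruptionError(ValueError):
    """Stream is truncated or its payload is inconsistent."""

    def __init__(self, message: str, byte_offset: int | None = None):
        if byte_offset is not None:
            message = f"{message} (at byte offset {byte_offset})"
        super().__init__(message)
        self.byte_offset = byte_offset


@dataclass(frozen=True)
class HuffmanCodebook:
    """Canonical prefix-free code over a signed-integer alphabet.

    ``lengths`` maps symbol -> code length; ``codes`` maps symbol ->
    (code value, code length) with codes assigned canonically: symbols
    sorted by (length, symbol) receive consecutive code values, shifted
    left at each length increase.
    """

    lengths: dict[int, int]
    codes: dict[int, tuple[int, int]]

    @classmethod
    def from_lengths(cls, lengths: dict[int, int]) -> "HuffmanCodebook":
        if not lengths:
            raise ValueError("empty codebook")
        for sym, ln in lengths.items():
            if ln < 1 or ln > 64:
                raise ValueError(f"invalid code length {ln} for symbol {sym}")
        codes: dict[int, tuple[int, int]] = {}
        code = 0
        prev_len = 0
        for sym in sorted(lengths, key=lambda s: (lengths[s], s)):
            ln = lengths[sym]
            code <<= ln - prev_len
            codes[sym] = (code, ln)
            code += 1
            prev_len = ln
        if len(lengths) > 1 and code > (1 << prev_len):
            raise ValueError("code lengths overflow the prefix code space")
        return cls(lengths=dict(lengths), codes=codes)

    def kraft_sum(self) -> float:
        return sum(2.0 ** -ln for ln in self.lengths.values())

    def mean_code_length(self, freqs: dict[int, int]) -> float:
        total = sum(freqs.values())
        return sum(self.lengths[s] * n for s, n in freqs.items()) / total


def build_codebook(freqs: dict[int, int]) -> HuffmanCodebook:
    """Optimal prefix code for the given symbol frequencies.

    Ties in the tree construction are broken by (count, symbol) ordering of
    the leaves (internal nodes by creation order), so identical frequency
    tables always produce identical codebooks.  A single-symbol alphabet
    gets a 1-bit code.
    """
    if not freqs:
        raise ValueError("empty frequency table")
    for sym, n in freqs.items():
        if n <= 0:
            raise ValueError(f"non-positive count {n} for symbol {sym}")
    if len(freqs) == 1:
        sym = next(iter(freqs))
        return HuffmanCodebook.from_lengths({sym: 1})

    # Heap items: (weight, kind, key, payload). Leaves sort before internal
    # nodes of equal weight and among themselves by symbol; internal nodes
    # by creation order. Payload is a symbol list whose depths we track.
    heap: list[tuple[int, int, int, list[int]]] = []
    depths = {sym: 0 for sym in freqs}
    for sym in sorted(freqs, key=lambda s: (freqs[s], s)):
        heap.append((freqs[sym], 0, sym, [sym]))
    heapq.heapify(heap)
    counter = 0
    while len(heap) > 1:
        w1, _, _, syms1 = heapq.heappop(heap)
        w2, _, _, syms2 = heapq.heappop(heap)
        merged = syms1 + syms2
        for s in merged:
            depths[s] += 1
        heapq.heappush(heap, (w1 + w2, 1, counter, merged))
        counter += 1
    return HuffmanCodebook.from_lengths(depths)


def _symbol_stream(coeffs: CoeffGrid) -> np.ndarray:
    """Flatten coefficients channel-major, each plane row-major."""
    return coeffs.values.transpose(2, 0, 1).ravel()


def _pack_bits(symbols: np.ndarray, codes: dict[int, tuple[int, int]]) -> tuple[bytes, int]:
    acc = 0
    nbits = 0
    total_bits = 0
    out = bytearray()
    for sym in symbols.tolist():
        code, ln = codes[sym]
        acc = (acc << ln) | code
        nbits += ln
        total_bits += ln
        while nbits >= 8:
            nbits -= 8
            out.append((acc >> nbits) & 0xFF)
        acc &= (1 << nbits) - 1
    if nbits:
        out.append((acc << (8 - nbits)) & 0xFF)
    return bytes(out), total_bits


def encode(coeffs: CoeffGrid, spec: PyramidSpec) -> bytes:
    """Serialize a coefficient grid plus its pyramid geometry to `.tdc` bytes."""
    symbols = _symbol_stream(coeffs)
    uniq, counts = np.unique(symbols, return_counts=True)
    book = build_codebook(dict(zip(uniq.tolist(), counts.tolist())))
    payload, nbits = _pack_bits(symbols, book.codes)

    parts = [
        _HEADER.pack(
            MAGIC,
            VERSION,
            spec.height,
            spec.width,
            spec.channels,
            spec.bit_depth,
            spec.levels,
            len(book.lengths),
        )
    ]
    for sym in sorted(book.lengths):
        parts.append(_ENTRY.pack(sym, book.lengths[sym]))
    parts.append(_BITCOUNT.pack(nbits))
    parts.append(payload)
    return b"".join(parts)


def _unpack_payload(
    payload: bytes, nbits: int, nsymbols: int, book: HuffmanCodebook, offset: int
) -> np.ndarray:
    # Canonical decoding tables: per code length, the first/last code value
    # and the index of the first symbol of that length.
    by_len: dict[int, list[int]] = {}
    for sym in sorted(book.lengths, key=lambda s: (book.lengths[s], s)):
        by_len.setdefault(book.lengths[sym], []).append(sym)
    first_code: dict[int, int] = {}
    last_code: dict[int, int] = {}
    syms_at: dict[int, list[int]] = {}
    for ln, syms in by_len.items():
        first_code[ln] = book.codes[syms[0]][0]
        last_code[ln] = book.codes[syms[-1]][0]
        syms_at[ln] = syms
    max_len = max(by_len)

    bits = np.unpackbits(np.frombuffer(payload, dtype=np.uint8))
    if bits.shape[0] < nbits:
        raise CorruptionError(
            f"payload truncated: {bits.shape[0]} bits present, {nbits} declared",
            byte_offset=offset + len(payload),
        )
    bits = bits[:nbits].tolist()

    out = np.empty(nsymbols, dtype=np.int64)
    pos = 0
    code = 0
    ln = 0
    produced = 0
    for bit in bits:
        code = (code << 1) | bit
        ln += 1
        pos += 1
        fc = first_code.get(ln)
        if fc is not None and fc <= code <= last_code[ln]:
            out[produced] = syms_at[ln][code - fc]
            produced += 1
            if produced == nsymbols:
                break
            code = 0
            ln = 0
        elif ln > max_len:
            raise CorruptionError(
                f"invalid code of length {ln} at bit {pos}",
                byte_offset=offset + pos // 8,
            )
    if produced < nsymbols:
        raise CorruptionError(
            f"payload exhausted after {produced} of {nsymbols} symbols",
            byte_offset=offset + (nbits + 7) // 8,
        )
    if pos != nbits:
        raise CorruptionError(
            f"payload bit count mismatch: consumed {pos}, declared {nbits}",
            byte_offset=offset + pos // 8,
        )
    return out


def decode(stream: bytes) -> tuple[CoeffGrid, PyramidSpec]:
    """Parse `.tdc` bytes back into the coefficient grid and pyramid spec."""
    if len(stream) < _HEADER.size:
        raise FormatError(f"stream too short for header ({len(stream)} bytes)")
    magic, version, height, width, channels, bit_depth, levels, nentries = (
        _HEADER.unpack_from(stream, 0)
    )
    if magic != MAGIC:
        raise FormatError(f"bad magic {magic!r}, expected {MAGIC!r}")
    if version != VERSION:
        raise FormatError(f"unsupported version {version}")
    offset = _HEADER.size
    end_entries = offset + nentries * _ENTRY.size
    if len(stream) < end_entries + _BITCOUNT.size:
        raise CorruptionError("stream truncated in codebook", byte_offset=len(stream))
    lengths: dict[int, int] = {}
    for _ in range(nentries):
        sym, ln = _ENTRY.unpack_from(stream, offset)
        lengths[sym] = ln
        offset += _ENTRY.size
    try:
        book = HuffmanCodebook.from_lengths(lengths)
    except ValueError as exc:
        raise CorruptionError(f"invalid codebook: {exc}", byte_offset=offset) from exc
    (nbits,) = _BITCOUNT.unpack_from(stream, offset)
    offset += _BITCOUNT.size
    payload = stream[offset:]
    if len(payload) < (nbits + 7) // 8:
        raise CorruptionError(
            f"payload truncated: {len(payload)} bytes for {nbits} bits",
            byte_offset=len(stream),
        )

    nsymbols = height * width * channels
    flat = _unpack_payload(payload, nbits, nsymbols, book, offset)
    values = flat.reshape(channels, height, width).transpose(1, 2, 0)
    spec = PyramidSpec(
        height=height,
        width=width,
        channels=channels,
        bit_depth=bit_depth,
        levels=levels,
    )
    return CoeffGrid(values=values, bit_depth=bit_depth), spec


def compress_grid(grid: PixelGrid, levels: int | str = "max") -> bytes:
    """Full pipeline: decompose ``grid`` and entropy-code the coefficients."""
    if levels == "max":
        levels = max(1, max_levels(grid.height, grid.width))
    coeffs, spec = decompose(grid, int(levels))
    return encode(coeffs, spec)


def decompress_grid(stream: bytes) -> PixelGrid:
    """Full inverse pipeline: decode a `.tdc` stream and reconstruct the image."""
    coeffs, spec = decode(stream)
    return reconstruct(coeffs, spec)
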