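"""Unit and property tests for the 1D/2D difference transform."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from difftx.dt_core import (
    FILTER_TAPS,
    CoeffGrid,
    PixelGrid,
    forward_1d,
    forward_2d,
    forward_plane,
    inverse_1d,
    inverse_2d,
    inverse_plane,
)

from conftest import random_grid


# ------------------------------------------------------------- oracles ----

def naive_forward_plane(f):
    """Literal double-loop transform: floor((left+right)/2) - sample at odd
    positions along rows (WH), columns (WV) and the diagonal (WD), with
    out-of-range even neighbors clamped.  Independent of the vectorized path.
    """
    f = [[int(v) for v in row] for row in np.asarray(f)]
    H, W = len(f), len(f[0])
    hs, ws = (H + 1) // 2, (W + 1) // 2
    out = [[0] * W for _ in range(H)]

    def ev(i, limit):  # clamp to last even index
        return min(i, 2 * ((limit - 1) // 2))

    for m in range(hs):
        for n in range(ws):
            out[m][n] = f[2 * m][2 * n]  # WS
    for m in range(hs):
        for n in range(W // 2):
            r, c = 2 * m, 2 * n + 1
            avg = (f[r][c - 1] + f[r][ev(c + 1, W)]) // 2
            out[m][ws + n] = avg - f[r][c]  # WH
    for m in range(H // 2):
        for n in range(ws):
            r, c = 2 * m + 1, 2 * n
            avg = (f[r - 1][c] + f[ev(r + 1, H)][c]) // 2
            out[hs + m][n] = avg - f[r][c]  # WV
    for m in range(H // 2):
        for n in range(W // 2):
            r, c = 2 * m + 1, 2 * n + 1
            avg = (f[r - 1][c - 1] + f[ev(r + 1, H)][ev(c + 1, W)]) // 2
            out[hs + m][ws + n] = avg - f[r][c]  # WD
    return np.array(out, dtype=np.int64)


# ------------------------------------------------------------ 1D cases ----

class TestForward1D:
    def test_constant_signal(self):
        evens, details = forward_1d([7, 7, 7, 7])
        assert evens.tolist() == [7, 7]
        assert details.tolist() == [0, 0]

    def test_linear_ramp_with_edge_replication(self):
        evens, details = forward_1d([10, 12, 14, 16])
        assert evens.tolist() == [10, 14]
        assert details.tolist() == [0, -2]

    def test_extreme_detail(self):
        evens, details = forward_1d([0, 255, 0], bit_depth=8)
        assert evens.tolist() == [0, 0]
        assert details.tolist() == [-255]

    def test_positive_extreme(self):
        _, details = forward_1d([255, 0, 255], bit_depth=8)
        assert details.tolist() == [255]

    def test_length_concatenation(self, rng):
        for L in (3, 4, 5, 10, 11):
            seq = rng.integers(0, 256, L)
            evens, details = forward_1d(seq)
            assert len(evens) + len(details) == L
            assert len(evens) == (L + 1) // 2

    def test_too_short_raises(self):
        with pytest.raises(ValueError, match="length"):
            forward_1d([1, 2])

    def test_negative_values_raise(self):
        with pytest.raises(ValueError):
            forward_1d([1, -2, 3])

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            forward_1d([0, 300, 0], bit_depth=8)

    def test_non_integer_raises(self):
        with pytest.raises(TypeError):
            forward_1d([1.0, 2.0, 3.0])


class TestInverse1D:
    def test_constant(self):
        assert inverse_1d([7, 7], [0, 0], 4).tolist() == [7, 7, 7, 7]

    def test_ramp(self):
        assert inverse_1d([10, 14], [0, -2], 4).tolist() == [10, 12, 14, 16]

    def test_inconsistent_lengths_raise(self):
        with pytest.raises(ValueError, match="[Ii]nconsistent"):
            inverse_1d([1, 2, 3], [0], 4)

    def test_round_trip_battery(self, rng):
        for _ in range(1000):
            L = int(rng.integers(3, 65))
            depth = int(rng.choice([8, 16]))
            seq = rng.integers(0, 1 << depth, L)
            evens, details = forward_1d(seq, bit_depth=depth)
            assert inverse_1d(evens, details, L).tolist() == seq.tolist()


@given(
    seq=st.lists(st.integers(0, 65535), min_size=3, max_size=64),
)
@settings(max_examples=200, deadline=None)
def test_round_trip_1d_property(seq):
    evens, details = forward_1d(seq, bit_depth=16)
    assert inverse_1d(evens, details, len(seq)).tolist() == seq


def test_filter_taps_zero_sum_and_symmetric():
    assert sum(FILTER_TAPS) == 0
    assert FILTER_TAPS[0] == FILTER_TAPS[2]


# ------------------------------------------------------------ 2D cases ----

class TestForward2D:
    def test_constant_plane(self):
        grid = PixelGrid(np.full((4, 4, 1), 9), bit_depth=8)
        coeffs = forward_2d(grid)
        c = coeffs.values[:, :, 0]
        assert np.array_equal(c[:2, :2], np.full((2, 2), 9))  # WS
        assert not c[:2, 2:].any() and not c[2:, :].any()  # WH, WV, WD

    def test_diagonal_ramp_details_small(self):
        f = np.add.outer(np.arange(5), np.arange(5))  # f(x,y) = x + y, 0..8
        grid = PixelGrid(f[:, :, np.newaxis], bit_depth=8)
        coeffs = forward_2d(grid)
        c = coeffs.values[:, :, 0]
        assert np.array_equal(c[:3, :3], f[::2, ::2])  # WS is the even grid
        details = np.concatenate([c[:3, 3:].ravel(), c[3:, :].ravel()])
        assert set(details.tolist()) <= {0, -1}
        assert inverse_2d(coeffs) == grid

    def test_matches_naive_oracle(self, rng):
        for shape in [(8, 8), (9, 7), (7, 9), (3, 3), (4, 5)]:
            f = rng.integers(0, 256, shape)
            assert np.array_equal(forward_plane(f), naive_forward_plane(f))

    def test_alphabet_bound_8bit(self, rng):
        for _ in range(20):
            grid = random_grid(rng, 16, 16, bit_depth=8)
            c = forward_2d(grid).values[:, :, 0]
            details = np.concatenate([c[:8, 8:].ravel(), c[8:, :].ravel()])
            assert details.min() >= -(1 << 8) and details.max() <= 1 << 8

    def test_count_conservation(self, rng):
        for shape in [(3, 3), (9, 7), (8, 8)]:
            grid = random_grid(rng, *shape)
            assert forward_2d(grid).values.size == grid.samples.size

    def test_too_small_raises(self):
        with pytest.raises(ValueError):
            forward_plane(np.zeros((2, 5), dtype=np.int64))


class TestInverse2D:
    def test_constant_round_trip(self):
        grid = PixelGrid(np.full((4, 4, 1), 9), bit_depth=8)
        assert inverse_2d(forward_2d(grid)) == grid

    def test_round_trip_all_parities_and_depths(self, rng):
        for H, W in [(3, 3), (3, 4), (4, 3), (4, 4), (9, 7), (8, 8), (17, 16)]:
            for depth in (8, 16):
                for channels in (1, 3):
                    grid = random_grid(rng, H, W, channels, depth)
                    assert inverse_2d(forward_2d(grid)) == grid

    def test_pass_order_independence(self, rng):
        f = rng.integers(0, 256, (8, 8))
        c = forward_plane(f)
        results = [
            inverse_plane(c, 8, 8, pass_order=order)
            for order in itertools.permutations(("H", "V", "D"))
        ]
        for r in results[1:]:
            assert np.array_equal(r, results[0])
        assert np.array_equal(results[0], f)

    def test_malformed_layout_raises(self):
        with pytest.raises(ValueError, match="shape"):
            inverse_plane(np.zeros((4, 4), dtype=np.int64), 5, 5)

    def test_bad_pass_order_raises(self):
        with pytest.raises(ValueError, match="pass_order"):
            inverse_plane(np.zeros((4, 4), dtype=np.int64), 4, 4, ("H", "H", "D"))


def test_attained_extremes_witnessed():
    # [0,255,0] pattern along a row: detail hits -(2^N - 1); the complement
    # hits +(2^N - 1).  Both stay strictly inside [-2^N, 2^N].
    f = np.zeros((3, 3), dtype=np.int64)
    f[0, 1] = 255
    assert forward_plane(f)[0, 2] == -255
    g = np.full((3, 3), 255, dtype=np.int64)
    g[0, 1] = 0
    assert forward_plane(g)[0, 2] == 255


class TestPixelGrid:
    def test_validates_range(self):
        with pytest.raises(ValueError):
            PixelGrid(np.full((3, 3, 1), 256), bit_depth=8)

    def test_validates_min_size(self):
        with pytest.raises(ValueError):
            PixelGrid(np.zeros((2, 3, 1), dtype=int), bit_depth=8)

    def test_validates_channels(self):
        with pytest.raises(ValueError):
            PixelGrid(np.zeros((3, 3, 2), dtype=int), bit_depth=8)

    def test_2d_input_promoted_to_single_channel(self):
        g = PixelGrid(np.zeros((3, 3), dtype=int), bit_depth=8)
        assert g.channels == 1


class TestCoeffGrid:
    def test_rejects_floats(self):
        with pytest.raises(TypeError):
            CoeffGrid(np.zeros((3, 3, 1)), bit_depth=8)
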