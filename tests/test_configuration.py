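"""Unlike-adjacency, UA bounds and the Landscape Configuration Index."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from foresttraj.configuration import (
    DegenerateConfigurationError,
    arrange_max,
    arrange_min,
    bounds_table,
    exhaustive_bounds,
    grid_lci,
    lci,
    ua_bounds,
    unlike_adjacency,
    unlike_adjacency_batch,
)


def ua_oracle(mask):
    """Independent enumeration: for every True pixel, count False Queen
    neighbours; each mixed pair is counted exactly once this way."""
    rows, cols = mask.shape
    total = 0
    for r in range(rows):
        for c in range(cols):
            if not mask[r, c]:
                continue
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == dc == 0:
                        continue
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < rows and 0 <= cc < cols and not mask[rr, cc]:
                        total += 1
    return total


class TestUnlikeAdjacency:
    def test_single_interior_pixel_has_eight_mixed_pairs(self):
        m = np.zeros((18, 18), bool)
        m[9, 9] = True
        assert unlike_adjacency(m) == 8

    def test_single_corner_pixel_has_three_mixed_pairs(self):
        m = np.zeros((18, 18), bool)
        m[0, 0] = True
        assert unlike_adjacency(m) == 3

    def test_single_edge_pixel_has_five_mixed_pairs(self):
        m = np.zeros((18, 18), bool)
        m[0, 9] = True
        assert unlike_adjacency(m) == 5

    def test_two_by_two_corner_block(self):
        m = np.zeros((18, 18), bool)
        m[:2, :2] = True
        assert unlike_adjacency(m) == ua_oracle(m) == 9

    def test_matches_pair_enumeration_oracle_on_random_grids(self, rng):
        for _ in range(300):
            rows = int(rng.integers(2, 19))
            cols = int(rng.integers(2, 19))
            m = rng.random((rows, cols)) < rng.uniform(0.05, 0.95)
            assert unlike_adjacency(m) == ua_oracle(m)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.integers(0, 2**25 - 1))
    def test_swap_symmetry(self, bits):
        m = np.array([(bits >> i) & 1 for i in range(25)], bool).reshape(5, 5)
        assert unlike_adjacency(m) == unlike_adjacency(~m)

    def test_batch_agrees_with_scalar(self, rng):
        masks = rng.random((40, 6, 7)) < 0.4
        batch = unlike_adjacency_batch(masks)
        assert [unlike_adjacency(m) for m in masks] == batch.tolist()


class TestBounds:
    def test_empty_and_full_grids_have_zero_bounds(self):
        for k in (0, 324):
            b = ua_bounds(k, 18, 18)
            assert (b.ua_min, b.ua_max) == (0, 0)

    def test_single_pixel_bounds_are_corner_and_core(self):
        b = ua_bounds(1, 18, 18)
        assert (b.ua_min, b.ua_max) == (3, 8)

    def test_constructive_equals_exhaustive_on_4x4_for_every_k(self):
        from foresttraj.configuration import _bounds_constructive

        assert exhaustive_bounds(4, 4).equals(_bounds_constructive(4, 4))

    def test_extremal_arrangements_attain_tabulated_bounds(self):
        tab = bounds_table(18, 18)
        for k in [0, 1, 7, 40, 100, 162, 200, 280, 323, 324]:
            assert unlike_adjacency(arrange_min(k, 18, 18)) == tab.ua_min[k]
            assert unlike_adjacency(arrange_max(k, 18, 18)) == tab.ua_max[k]
            assert arrange_min(k, 18, 18).sum() == k
            assert arrange_max(k, 18, 18).sum() == k

    def test_random_arrangements_never_violate_bounds(self, rng):
        tab = bounds_table(18, 18)
        for k in [1, 20, 81, 162, 243, 300, 323]:
            masks = np.zeros((2000, 324), bool)
            for i in range(2000):
                masks[i, rng.choice(324, k, replace=False)] = True
            ua = unlike_adjacency_batch(masks.reshape(-1, 18, 18))
            assert ua.min() >= tab.ua_min[k]
            assert ua.max() <= tab.ua_max[k]

    def test_shipped_table_matches_regeneration(self):
        from foresttraj.configuration import _bounds_constructive

        assert bounds_table(18, 18).equals(_bounds_constructive(18, 18))

    def test_k_out_of_range_raises(self):
        with pytest.raises(ValueError):
            ua_bounds(-1, 18, 18)
        with pytest.raises(ValueError):
            ua_bounds(325, 18, 18)


class TestLCI:
    def test_endpoints_and_midpoint(self):
        b = ua_bounds(40, 18, 18)
        assert lci(b.ua_min, b).lci == 0.0
        assert lci(b.ua_max, b).lci == 1.0
        mid = (b.ua_min + b.ua_max) / 2
        assert lci(mid, b).lci == pytest.approx(0.5)

    def test_degenerate_bounds_raise(self):
        with pytest.raises(DegenerateConfigurationError):
            lci(0, ua_bounds(0, 18, 18))
        with pytest.raises(DegenerateConfigurationError):
            lci(0, ua_bounds(324, 18, 18))

    def test_lci_in_unit_interval_for_random_grids(self, rng):
        for _ in range(200):
            m = rng.random((18, 18)) < rng.uniform(0.05, 0.95)
            if 0 < m.sum() < 324:
                assert 0.0 <= grid_lci(m).lci <= 1.0
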