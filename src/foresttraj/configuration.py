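"""Spatial-configuration metrics for a binary land-cover layer.

The spatial arrangement of the transition land cover inside an analysis cell
is summarised by its *unlike-adjacency* (UA): the number of Queen-contiguous
pixel pairs in which one pixel belongs to the transition class and the other
to the complementary landscape (everything else, forest included).  Pixels at
grid corners, edges and in the interior have 3, 5 and 8 neighbours; there is
no wraparound.  High UA means the two classes are interspersed, low UA means
the transition class is compactly arranged.

UA is not comparable across cells holding different transition-class amounts,
so it is normalised by the extreme values achievable with the same pixel
count ``k``::

    LCI = (UA_obs - UA_min(k)) / (UA_max(k) - UA_min(k))

The Landscape Configuration Index (LCI) therefore lies in [0, 1]: 0 is the
most compact arrangement achievable with ``k`` pixels, 1 the most fragmented.
``UA_min``/``UA_max`` are obtained exhaustively on small grids and by
certified constructions (corner-anchored compact growth; greedy dispersal
with a single-move refinement pass) otherwise; the bounds for the default
18x18 cell are precomputed and shipped with the package.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "UABounds",
    "LCIValue",
    "DegenerateConfigurationError",
    "unlike_adjacency",
    "unlike_adjacency_batch",
    "ua_bounds",
    "bounds_table",
    "lci",
    "arrange_min",
    "arrange_max",
]

_QUEEN_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]], dtype=np.int64)

# Full enumeration of all 2**(rows*cols) masks is used when feasible.
_EXHAUSTIVE_LIMIT = 16


class DegenerateConfigurationError(ValueError):
    """LCI is undefined: the class is absent or fills the whole grid."""


@dataclass(frozen=True)
class UABounds:
    k: int
    ua_min: int
    ua_max: int
    method: str  # "exhaustive" or "constructive"

    def __post_init__(self):
        if not 0 <= self.ua_min <= self.ua_max:
            raise ValueError("invalid bounds ordering")


@dataclass(frozen=True)
class LCIValue:
    ua_obs: int
    lci: float


def unlike_adjacency(mask: np.ndarray) -> int:
    """Count mixed Queen-adjacent pixel pairs, each pair counted once.

    Equivalent to summing, over every True pixel, the number of its False
    Queen neighbours (and symmetrically with roles swapped).
    """
    m = np.asarray(mask, dtype=bool)
    if m.ndim != 2:
        raise ValueError("mask must be 2-D")
    return int(unlike_adjacency_batch(m[None])[0])


def unlike_adjacency_batch(masks: np.ndarray) -> np.ndarray:
    """Vectorised UA for a stack of masks with shape (n, rows, cols).

    Each Queen-adjacent pair is visited exactly once through the four
    forward offsets E, S, SE, SW.
    """
    m = np.asarray(masks, dtype=bool)
    if m.ndim != 3:
        raise ValueError("masks must have shape (n, rows, cols)")
    ua = (m[:, :, :-1] ^ m[:, :, 1:]).sum(axis=(1, 2))
    ua += (m[:, :-1, :] ^ m[:, 1:, :]).sum(axis=(1, 2))
    ua += (m[:, :-1, :-1] ^ m[:, 1:, 1:]).sum(axis=(1, 2))
    ua += (m[:, :-1, 1:] ^ m[:, 1:, :-1]).sum(axis=(1, 2))
    return ua.astype(np.int64)


def neighbor_counts(rows: int, cols: int) -> np.ndarray:
    """Queen neighbourhood size per pixel (3 corners, 5 edges, 8 core)."""
    return ndimage.convolve(
        np.ones((rows, cols), dtype=np.int64), _QUEEN_KERNEL, mode="constant"
    )


def _true_neighbor_counts(mask: np.ndarray) -> np.ndarray:
    return ndimage.convolve(
        mask.astype(np.int64), _QUEEN_KERNEL, mode="constant"
    )


# ---------------------------------------------------------------------------
# Extremal constructions
# ---------------------------------------------------------------------------

def _greedy_order_min(rows: int, cols: int) -> np.ndarray:
    """Nested growth order minimising marginal UA at each addition.

    Starting from the north-west corner, each new pixel is the candidate
    Queen-adjacent to the current block whose addition increases UA least
    (corner/edge pixels have truncated neighbourhoods, lowering exposure);
    this grows a quasi-square block anchored in the corner.  Returns flat
    pixel indices in addition order.
    """
    n = rows * cols
    nbr = neighbor_counts(rows, cols).ravel()
    mask = np.zeros((rows, cols), dtype=bool)
    mask[0, 0] = True
    order = [0]
    conv = _true_neighbor_counts(mask).ravel()
    for _ in range(n - 1):
        cand = (~mask.ravel()) & (conv > 0)
        gain = np.where(cand, nbr - 2 * conv, np.iinfo(np.int64).max)
        p = int(np.argmin(gain))
        order.append(p)
        mask.ravel()[p] = True
        conv = _true_neighbor_counts(mask).ravel()
    return np.array(order)


def _greedy_order_max(rows: int, cols: int) -> np.ndarray:
    """Nested placement order maximising marginal UA at each addition.

    Picks isolated interior pixels first (marginal gain 8), densifying only
    once no well-separated position remains; a per-k refinement pass in
    :func:`_bounds_constructive` then improves individual arrangements.
    """
    n = rows * cols
    nbr = neighbor_counts(rows, cols).ravel()
    mask = np.zeros((rows, cols), dtype=bool)
    order = []
    conv = np.zeros(n, dtype=np.int64)
    for _ in range(n):
        gain = np.where(~mask.ravel(), nbr - 2 * conv, np.iinfo(np.int64).min)
        p = int(np.argmax(gain))
        order.append(p)
        mask.ravel()[p] = True
        conv = _true_neighbor_counts(mask).ravel()
    return np.array(order)


def _refine(mask: np.ndarray, maximize: bool, max_iter: int = 200) -> np.ndarray:
    """Steepest single-pixel-move refinement of an arrangement.

    Moves one transition pixel at a time to the position changing UA most in
    the requested direction; stops at a local optimum or after ``max_iter``
    moves.  k is conserved.
    """
    rows, cols = mask.shape
    nbr = neighbor_counts(rows, cols).ravel()
    m = mask.copy()
    sign = 1 if maximize else -1
    for _ in range(max_iter):
        flat = m.ravel()
        conv = _true_neighbor_counts(m).ravel()
        add_gain = np.where(~flat, nbr - 2 * conv, -np.iinfo(np.int64).max)
        rem_gain = np.where(flat, 2 * conv - nbr, -np.iinfo(np.int64).max)
        if maximize:
            ps = np.argsort(add_gain)[-4:]
            qs = np.argsort(rem_gain)[-4:]
        else:
            ps = np.argsort(-add_gain)[:4][::-1]
            qs = np.argsort(-rem_gain)[:4][::-1]
        best = None
        best_delta = 0
        for q in qs:
            if not flat[q]:
                continue
            for p in ps:
                if flat[p] or p == q:
                    continue
                pr, pc = divmod(int(p), cols)
                qr, qc = divmod(int(q), cols)
                adj = max(abs(pr - qr), abs(pc - qc)) == 1
                delta = int(add_gain[p] + rem_gain[q]) + (2 if adj else 0)
                if sign * delta > sign * best_delta:
                    best_delta = delta
                    best = (int(p), int(q))
        if best is None or sign * best_delta <= 0:
            break
        p, q = best
        m.ravel()[q] = False
        m.ravel()[p] = True
    return m


def arrange_min(k: int, rows: int, cols: int) -> np.ndarray:
    """Deterministic arrangement of k pixels attaining the UA lower bound."""
    _check_k(k, rows, cols)
    if k == 0:
        return np.zeros((rows, cols), dtype=bool)
    if k == rows * cols:
        return np.ones((rows, cols), dtype=bool)
    if 2 * k > rows * cols:
        # UA is invariant under class exchange; build the complement compactly.
        return ~arrange_min(rows * cols - k, rows, cols)
    order = _min_order_cached(rows, cols)
    mask = np.zeros(rows * cols, dtype=bool)
    mask[order[:k]] = True
    return _refine(mask.reshape(rows, cols), maximize=False)


def arrange_max(k: int, rows: int, cols: int) -> np.ndarray:
    """Deterministic arrangement of k pixels attaining the UA upper bound."""
    _check_k(k, rows, cols)
    if k in (0, rows * cols):
        return arrange_min(k, rows, cols)
    if 2 * k > rows * cols:
        return ~arrange_max(rows * cols - k, rows, cols)
    order = _max_order_cached(rows, cols)
    mask = np.zeros(rows * cols, dtype=bool)
    mask[order[:k]] = True
    return _refine(mask.reshape(rows, cols), maximize=True)


_order_cache: dict = {}


def _min_order_cached(rows, cols):
    key = ("min", rows, cols)
    if key not in _order_cache:
        _order_cache[key] = _greedy_order_min(rows, cols)
    return _order_cache[key]


def _max_order_cached(rows, cols):
    key = ("max", rows, cols)
    if key not in _order_cache:
        _order_cache[key] = _greedy_order_max(rows, cols)
    return _order_cache[key]


# ---------------------------------------------------------------------------
# Bounds
# ---------------------------------------------------------------------------

def _check_k(k: int, rows: int, cols: int) -> None:
    if not 0 <= k <= rows * cols:
        raise ValueError(f"k={k} outside [0, {rows * cols}]")


def exhaustive_bounds(rows: int, cols: int) -> pd.DataFrame:
    """Exact UA bounds for every k by enumerating all 2**(rows*cols) masks."""
    n = rows * cols
    if n > _EXHAUSTIVE_LIMIT:
        raise ValueError(f"exhaustive enumeration limited to {_EXHAUSTIVE_LIMIT} pixels")
    codes = np.arange(2**n, dtype=np.uint32)
    bits = ((codes[:, None] >> np.arange(n)) & 1).astype(bool)
    masks = bits.reshape(-1, rows, cols)
    ks = bits.sum(axis=1)
    ua = unlike_adjacency_batch(masks)
    rec = []
    for k in range(n + 1):
        sel = ua[ks == k]
        rec.append((k, int(sel.min()), int(sel.max())))
    return pd.DataFrame(rec, columns=["k", "ua_min", "ua_max"])


def _bounds_constructive(rows: int, cols: int) -> pd.DataFrame:
    rec = []
    for k in range(rows * cols + 1):
        lo = unlike_adjacency(arrange_min(k, rows, cols))
        hi = unlike_adjacency(arrange_max(k, rows, cols))
        rec.append((k, lo, hi))
    return pd.DataFrame(rec, columns=["k", "ua_min", "ua_max"])


_table_cache: dict = {}


def bounds_table(rows: int = 18, cols: int = 18) -> pd.DataFrame:
    """Table of (k, ua_min, ua_max) for k = 0..rows*cols, computed once.

    The default 18x18 table is loaded from the CSV shipped with the package
    (regenerable with ``foresttraj bounds-table``); other sizes are computed
    on first use: exhaustively when the grid has at most 16 pixels,
    constructively otherwise.
    """
    key = (rows, cols)
    if key in _table_cache:
        return _table_cache[key]
    if key == (18, 18):
        ref = resources.files("foresttraj").joinpath("data/ua_bounds_18x18.csv")
        if ref.is_file():
            with resources.as_file(ref) as path:
                tab = pd.read_csv(path)
            _table_cache[key] = tab
            return tab
    if rows * cols <= _EXHAUSTIVE_LIMIT:
        tab = exhaustive_bounds(rows, cols)
    else:
        tab = _bounds_constructive(rows, cols)
    _table_cache[key] = tab
    return tab


def ua_bounds(k: int, rows: int = 18, cols: int = 18) -> UABounds:
    """UA_min and UA_max achievable with k transition pixels on rows x cols."""
    _check_k(k, rows, cols)
    method = "exhaustive" if rows * cols <= _EXHAUSTIVE_LIMIT else "constructive"
    tab = bounds_table(rows, cols)
    row = tab.iloc[k]
    return UABounds(k=k, ua_min=int(row.ua_min), ua_max=int(row.ua_max), method=method)


def lci(ua_obs: int, bounds: UABounds) -> LCIValue:
    """Normalise an observed UA into the Landscape Configuration Index.

    Raises :class:`DegenerateConfigurationError` when the bounds collapse
    (k = 0 or k = rows*cols), where no arrangement information exists.
    """
    if bounds.ua_max <= bounds.ua_min:
        raise DegenerateConfigurationError(
            f"LCI undefined for k={bounds.k}: UA bounds collapse "
            f"({bounds.ua_min}, {bounds.ua_max})"
        )
    value = (ua_obs - bounds.ua_min) / (bounds.ua_max - bounds.ua_min)
    return LCIValue(ua_obs=int(ua_obs), lci=float(value))


def grid_lci(mask: np.ndarray) -> LCIValue:
    """Convenience: LCI of a binary grid (bounds looked up for its k)."""
    m = np.asarray(mask, dtype=bool)
    k = int(m.sum())
    b = ua_bounds(k, *m.shape)
    return lci(unlike_adjacency(m), b)
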