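"""Per-cell land-cover transition matrices and the dominant transition.

Change is assessed between the first and last maps of the series only.  The
transition matrix counts ordered (from, to) pixel changes over the pixels
whose category differs between the two maps (identity pairs are excluded:
"transition" denotes change, and the certainty share is only meaningful over
changed pixels).  The most frequent ordered pair is the *dominant LC
transition*; when it involves forest, its non-forest member is the cell's
*transition LC*, and the dominant count divided by the number of changed
pixels is the attribution certainty.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .categories import CATEGORY_ORDER, CATEGORY_CODES, FOREST

__all__ = ["TransitionMatrix", "DominantTransition", "transition_matrix", "dominant_transition"]

#: Deterministic tie-break order over category codes (the paper-silent case):
#: forest-involving pairs are preferred, then the fixed category order.
_TIE_ORDER = {CATEGORY_CODES[name]: i for i, name in enumerate(CATEGORY_ORDER)}


@dataclass(frozen=True)
class TransitionMatrix:
    """Counts of ordered (from, to) changes between two maps; no (c, c) keys."""

    counts: dict
    total_changed: int

    def __post_init__(self):
        if any(a == b for a, b in self.counts):
            raise ValueError("identity pairs are excluded from the matrix")
        if sum(self.counts.values()) != self.total_changed:
            raise ValueError("total_changed must equal the sum of counts")


@dataclass(frozen=True)
class DominantTransition:
    from_category: int
    to_category: int
    count: int
    certainty: float
    involves_forest: bool
    transition_lc: int | None
    tie: bool = False


def transition_matrix(first: np.ndarray, last: np.ndarray) -> TransitionMatrix:
    """Count ordered per-pixel category changes between two maps."""
    a = np.asarray(first)
    b = np.asarray(last)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    changed = a != b
    pairs, n = np.unique(
        np.stack([a[changed], b[changed]]), axis=1, return_counts=True
    )
    counts = {
        (int(f), int(t)): int(c) for (f, t), c in zip(pairs.T, n)
    }
    return TransitionMatrix(counts=counts, total_changed=int(changed.sum()))


def dominant_transition(
    m: TransitionMatrix, forest_class: int = FOREST
) -> DominantTransition | None:
    """Most frequent ordered transition, or None when nothing changed.

    Ties are broken deterministically: forest-involving pairs first, then
    the fixed category order on (from, to); tied maxima are flagged.
    """
    if m.total_changed == 0 or not m.counts:
        return None

    def sort_key(item):
        (f, t), c = item
        involves = forest_class in (f, t)
        return (-c, not involves, _TIE_ORDER.get(f, 99), _TIE_ORDER.get(t, 99))

    ranked = sorted(m.counts.items(), key=sort_key)
    (f, t), c = ranked[0]
    tie = sum(1 for _, cc in m.counts.items() if cc == c) > 1
    involves = forest_class in (f, t)
    transition_lc = (t if f == forest_class else f) if involves else None
    return DominantTransition(
        from_category=f,
        to_category=t,
        count=c,
        certainty=c / m.total_changed,
        involves_forest=involves,
        transition_lc=transition_lc,
        tie=tie,
    )
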