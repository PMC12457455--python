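"""Interval, amount, rate and persistence of per-cell forest change.

The *interval of forest change* runs from the last year before the first
change in forest-pixel count (S) to the first year after which the count no
longer changes (E); its duration is E - S inter-annual steps.  The relative
rate of change is 1/duration (year^-1), contrasting abrupt (rate near 1)
with gradual (rate near 1/(n_years-1)) trajectories; the amount of change is
the start-to-end difference in forest count as a proportion of the cell.
Trajectories are *persistent* when the count moves in one direction only
inside the interval (zero-change plateau years allowed) and *non-persistent*
when both loss and gain occur.  Initial conditions (amount and LCI of the
transition land cover) are taken from the year-S grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .configuration import (
    DegenerateConfigurationError,
    grid_lci,
)
from .series import LCSeries

__all__ = [
    "ForestSeries",
    "ChangeInterval",
    "CellRecord",
    "change_interval",
    "rate_of_change",
    "classify_trajectory",
    "amount_of_change",
    "initial_state",
    "apply_filters",
    "scale_min_change",
    "pixel_area",
]

EARTH_RADIUS_KM = 6371.0

#: min-change threshold on the default 324-pixel cell: cells with fewer than
#: 17 forest pixels changed (<= 5% of the cell) are excluded as noise.
DEFAULT_MIN_CHANGE_PIXELS = 17


@dataclass(frozen=True)
class ForestSeries:
    """Forest pixel count per year for one cell."""

    counts: np.ndarray
    cell_size: int = 324

    def __post_init__(self):
        c = np.asarray(self.counts, dtype=int)
        object.__setattr__(self, "counts", c)
        if c.ndim != 1 or c.size < 2:
            raise ValueError("need a 1-D series of at least 2 years")
        if (c < 0).any() or (c > self.cell_size).any():
            raise ValueError("forest counts outside [0, cell_size]")

    @classmethod
    def from_series(cls, series: LCSeries, forest_class: int) -> "ForestSeries":
        return cls(series.class_counts(forest_class), cell_size=series.cell_size)

    @property
    def proportions(self) -> np.ndarray:
        return self.counts / self.cell_size


@dataclass(frozen=True)
class ChangeInterval:
    start: int  # S: last year index before any change
    end: int  # E: first year index from which the count is constant

    @property
    def duration(self) -> int:
        return self.end - self.start

    def __post_init__(self):
        if not 0 <= self.start < self.end:
            raise ValueError("need 0 <= start < end")


def change_interval(fs: ForestSeries) -> ChangeInterval | None:
    """Locate the interval of forest change; None when the series is constant."""
    c = fs.counts
    changed = np.flatnonzero(np.diff(c) != 0)
    if changed.size == 0:
        return None
    return ChangeInterval(start=int(changed[0]), end=int(changed[-1]) + 1)


def rate_of_change(interval: ChangeInterval) -> float:
    """Relative rate of forest change: reciprocal of the duration in years."""
    return 1.0 / interval.duration


def classify_trajectory(fs: ForestSeries, interval: ChangeInterval | None) -> str:
    """persistent_loss / persistent_gain / non_persistent / no_change.

    Persistence is read non-strictly: zero-change plateau years inside the
    interval do not break a monotone trajectory.
    """
    if interval is None:
        return "no_change"
    d = np.diff(fs.counts[interval.start: interval.end + 1])
    has_loss = (d < 0).any()
    has_gain = (d > 0).any()
    if has_loss and has_gain:
        return "non_persistent"
    if has_loss:
        return "persistent_loss"
    if has_gain:
        return "persistent_gain"
    return "no_change"


def amount_of_change(fs: ForestSeries, interval: ChangeInterval) -> float:
    """|start-to-end difference in forest count| as a proportion of the cell."""
    return abs(int(fs.counts[interval.end]) - int(fs.counts[interval.start])) / fs.cell_size


def change_pixels(fs: ForestSeries, interval: ChangeInterval) -> int:
    return abs(int(fs.counts[interval.end]) - int(fs.counts[interval.start]))


def initial_state(
    cell: LCSeries, interval: ChangeInterval, transition_class: int
) -> tuple[float, float | None]:
    """(initial amount proportion, initial LCI) of the transition LC at year S.

    The LCI is None when the transition LC is absent or fills the grid at S
    (degenerate bounds; flagged for the validity filter downstream).
    """
    mask = cell.mask(interval.start, transition_class)
    amount = mask.sum() / mask.size
    try:
        value = grid_lci(mask).lci
    except DegenerateConfigurationError:
        value = None
    return float(amount), value


@dataclass
class CellRecord:
    """Per-cell derived quantities plus exclusion-filter flags."""

    cell_id: str
    from_category: int | None = None
    to_category: int | None = None
    transition_lc: int | None = None
    involves_forest: bool = False
    certainty: float | None = None
    tie: bool = False
    trajectory_class: str = "no_change"
    interval_start: int | None = None
    interval_end: int | None = None
    duration: int | None = None
    amount_of_change: float | None = None
    change_pixels: int | None = None
    rate_of_change: float | None = None
    initial_transition_amount: float | None = None
    initial_lci: float | None = None
    filter_flags: set = field(default_factory=set)

    @property
    def retained(self) -> bool:
        return not self.filter_flags


def scale_min_change(cell_size: int, base: int = DEFAULT_MIN_CHANGE_PIXELS) -> int:
    """Scale the min-change pixel threshold to other cell sizes.

    17 pixels on a 324-pixel cell marks ~5.25% of the grid; the same grid
    proportion is applied at other sizes.
    """
    return math.ceil(base / 324 * cell_size)


def apply_filters(
    records: list[CellRecord], min_change_pixels: int = DEFAULT_MIN_CHANGE_PIXELS
) -> tuple[list[CellRecord], list[CellRecord]]:
    """Split records into (retained, excluded), stamping exclusion reasons.

    Reasons: ``no_forest_transition`` (dominant transition missing or not
    involving forest), ``no_change``, ``min_change`` (fewer forest pixels
    changed than the threshold), ``non_persistent``, ``degenerate_lci``
    (transition LC absent or grid-filling at the interval start).  A record
    may carry several reasons; retained records carry none.
    """
    retained, excluded = [], []
    for r in records:
        if not r.involves_forest:
            r.filter_flags.add("no_forest_transition")
        if r.trajectory_class == "no_change":
            r.filter_flags.add("no_change")
        elif r.change_pixels is not None and r.change_pixels < min_change_pixels:
            r.filter_flags.add("min_change")
        if r.trajectory_class == "non_persistent":
            r.filter_flags.add("non_persistent")
        if r.trajectory_class in ("persistent_loss", "persistent_gain") and r.initial_lci is None:
            r.filter_flags.add("degenerate_lci")
        (excluded if r.filter_flags else retained).append(r)
    return retained, excluded


def pixel_area(
    cell_bounds: tuple[float, float, float, float], rows: int, cols: int
) -> float:
    """Mean pixel area (km^2) of a cell from its geographic bounds.

    ``cell_bounds`` is (lon_min, lat_min, lon_max, lat_max) in degrees.  The
    great-circle lengths of the cell's edges (spherical Earth, R = 6371 km)
    are divided by the number of columns/rows; the mean east-west edge is
    used so the estimate is the average pixel of the cell.
    """
    lon0, lat0, lon1, lat1 = cell_bounds
    if lon1 <= lon0 or lat1 <= lat0:
        raise ValueError("degenerate cell bounds")
    if max(abs(lat0), abs(lat1)) > 90:
        raise ValueError("latitude outside [-90, 90]")
    height = _haversine_km(lon0, lat0, lon0, lat1)
    width = 0.5 * (
        _haversine_km(lon0, lat0, lon1, lat0) + _haversine_km(lon0, lat1, lon1, lat1)
    )
    return (width / cols) * (height / rows)


def _haversine_km(lon0, lat0, lon1, lat1) -> float:
    p0, p1 = math.radians(lat0), math.radians(lat1)
    dl = math.radians(lon1 - lon0)
    dp = p1 - p0
    a = math.sin(dp / 2) ** 2 + math.cos(p0) * math.cos(p1) * math.sin(dl / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(math.sqrt(a))
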