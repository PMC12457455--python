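"""Synthetic annual land-cover grids with controlled change trajectories.

Generates per-cell categorical series that emulate the structural properties
the trajectory pipeline assumes: an 18x18-pixel cell observed over 29 annual
steps, eight IPCC categories, a controllable starting amount and spatial
arrangement (target LCI) of the transition land cover, and a controllable
forest-change trajectory (persistent gradual/abrupt/plateaued loss or gain,
or non-persistent mixed change).  All randomness is seeded; a noise-free
generated cell is recovered exactly by the downstream pipeline.

Forest <-> transition conversions happen preferentially at the interface
between the two classes (pixels Queen-adjacent to the other class), so that
intermediate arrangements remain spatially plausible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .categories import CATEGORY_CODES, FOREST, CROPLAND
from .configuration import (
    _true_neighbor_counts,
    grid_lci,
    lci,
    ua_bounds,
    unlike_adjacency,
    DegenerateConfigurationError,
)
from .series import LCSeries

__all__ = [
    "TrajectorySpec",
    "CellSpec",
    "arrange_binary",
    "generate_lc_series",
    "generate_mosaic",
    "apply_misclassification",
    "random_cell_specs",
]

_DIRECTIONS = ("loss", "gain", "non_persistent", "none")
_SHAPES = ("gradual", "abrupt", "plateaued", "mixed")


@dataclass(frozen=True)
class TrajectorySpec:
    """What the forest-pixel count should do over the series.

    ``change_pixels`` is the total number of forest pixels converted during
    the interval; for ``non_persistent`` it is the gross loss, part of which
    is subsequently regained.  ``shape`` controls how the change is spread
    over ``duration_years`` inter-annual steps starting after ``start_step``.
    """

    direction: str = "none"
    change_pixels: int = 0
    start_step: int = 0
    duration_years: int = 1
    shape: str = "gradual"

    def __post_init__(self):
        if self.direction not in _DIRECTIONS:
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.shape not in _SHAPES:
            raise ValueError(f"unknown shape {self.shape!r}")
        if self.change_pixels < 0:
            raise ValueError("change_pixels must be >= 0")
        if self.duration_years < 1:
            raise ValueError("duration_years must be >= 1")
        if self.shape == "abrupt" and self.duration_years != 1:
            raise ValueError("abrupt change implies duration_years == 1")
        if self.shape == "mixed" and self.direction != "non_persistent":
            raise ValueError("mixed shape is reserved for non_persistent")
        if self.direction == "non_persistent" and self.duration_years < 2:
            raise ValueError("non_persistent change needs duration >= 2")


@dataclass(frozen=True)
class CellSpec:
    """Full recipe for one synthetic cell."""

    n_years: int = 29
    cell_rows: int = 18
    cell_cols: int = 18
    forest_class: int = FOREST
    transition_class: int = CROPLAND
    initial_transition_amount: int = 60
    target_lci: float | None = None
    trajectory: TrajectorySpec = field(default_factory=TrajectorySpec)
    background_classes: tuple = ()
    background_amount: int = 0
    seed: int | None = None
    cell_id: str | None = None

    def __post_init__(self):
        n = self.cell_rows * self.cell_cols
        if not 0 <= self.initial_transition_amount <= n:
            raise ValueError("initial_transition_amount outside the grid")
        if self.forest_class == self.transition_class:
            raise ValueError("forest and transition class must differ")
        if self.target_lci is not None and not 0 <= self.target_lci <= 1:
            raise ValueError("target_lci outside [0, 1]")
        t = self.trajectory
        if t.direction != "none" and t.start_step + t.duration_years >= self.n_years:
            raise ValueError("trajectory does not fit inside the series")


def arrange_binary(
    k: int,
    rows: int,
    cols: int,
    target_lci: float | None = None,
    seed: int = 0,
    tol: float = 0.05,
    max_moves: int = 500,
) -> np.ndarray:
    """Place exactly k True pixels, optionally steering toward a target LCI.

    Without a target the placement is uniform at random (seeded).  With a
    target, a seeded random start is improved by steepest single-pixel moves
    on |UA - target UA| until the realised LCI is within ``tol`` of the
    target or no move helps (closest-achievable semantics); deterministic
    given the seed.
    """
    n = rows * cols
    if not 0 <= k <= n:
        raise ValueError(f"k={k} outside [0, {n}]")
    rng = np.random.default_rng(seed)
    mask = np.zeros(n, dtype=bool)
    mask[rng.choice(n, size=k, replace=False)] = True
    mask = mask.reshape(rows, cols)
    if target_lci is None:
        return mask
    if not 0 < k < n:
        raise ValueError("target_lci requires 0 < k < rows*cols")
    if not 0 <= target_lci <= 1:
        raise ValueError("target_lci outside [0, 1]")

    b = ua_bounds(k, rows, cols)
    target_ua = b.ua_min + target_lci * (b.ua_max - b.ua_min)
    nbr = _neighbor_counts_cached(rows, cols)
    # approach the target monotonically from the nearer certified extreme:
    # small single-pixel moves then walk UA toward the target without the
    # local optima a random start runs into
    from .configuration import arrange_max, arrange_min

    start = arrange_min(k, rows, cols) if target_lci <= 0.5 else arrange_max(k, rows, cols)
    if abs(unlike_adjacency(start) - target_ua) < abs(unlike_adjacency(mask) - target_ua):
        mask = start.copy()
    best = mask.copy()
    best_err = abs(unlike_adjacency(mask) - target_ua)
    for _ in range(max_moves):
        ua = unlike_adjacency(mask)
        err = abs(ua - target_ua)
        if err < best_err:
            best, best_err = mask.copy(), err
        if err / (b.ua_max - b.ua_min) <= tol:
            break
        flat = mask.ravel()
        conv = _true_neighbor_counts(mask).ravel()
        add_gain = nbr - 2 * conv  # UA change when turning a pixel on
        rem_gain = 2 * conv - nbr  # UA change when turning a pixel off
        # Best pair (turn q off, turn p on); adjacency correction is small
        # and absorbed by re-evaluating UA on the next iteration.
        # choose the move whose predicted UA lands closest to the target;
        # seeded jitter breaks ties so different seeds explore differently
        delta = add_gain[None, :] + rem_gain[:, None]
        pred_err = np.abs(ua + delta - target_ua) + rng.random(delta.shape) * 0.01
        pred_err[~flat, :] = np.inf  # q must currently be on
        pred_err[:, flat] = np.inf  # p must currently be off
        q, p = np.unravel_index(np.argmin(pred_err), pred_err.shape)
        if not np.isfinite(pred_err[q, p]):
            break
        new = mask.copy()
        new.ravel()[q] = False
        new.ravel()[p] = True
        if abs(unlike_adjacency(new) - target_ua) >= err:
            break  # local optimum: keep closest achievable
        mask = new
    ua = unlike_adjacency(mask)
    if abs(ua - target_ua) < best_err:
        best = mask
    return best


_nbr_cache: dict = {}


def _neighbor_counts_cached(rows, cols):
    from .configuration import neighbor_counts

    key = (rows, cols)
    if key not in _nbr_cache:
        _nbr_cache[key] = neighbor_counts(rows, cols).ravel()
    return _nbr_cache[key]


def _step_increments(traj: TrajectorySpec, rng: np.random.Generator) -> np.ndarray:
    """Signed forest-pixel change per inter-annual step of the interval.

    Positive = forest gain.  The first and last steps are always non-zero so
    the realised interval matches (start_step, duration_years) exactly.
    """
    c, d = traj.change_pixels, traj.duration_years
    if traj.direction == "none" or c == 0:
        return np.zeros(d, dtype=int)
    sign = -1 if traj.direction == "loss" else 1
    if traj.direction == "non_persistent":
        # gross loss c over the first half, partial regain over the second
        m = max(1, d // 2)
        gain_total = max(d - m, c // 2)
        inc = np.concatenate(
            [-_spread(c, m, rng), _spread(gain_total, d - m, rng)]
        )
        return inc
    if traj.shape == "abrupt":
        return np.array([sign * c])
    if traj.shape == "gradual":
        return sign * _spread(c, d, rng)
    if traj.shape == "plateaued":
        # zero-change years strictly inside the interval
        n_zero = min(d - 2, max(1, d // 3)) if d > 2 else 0
        active = d - n_zero
        inc = np.zeros(d, dtype=int)
        interior = rng.choice(np.arange(1, d - 1), size=n_zero, replace=False) if n_zero else []
        act_slots = np.setdiff1d(np.arange(d), interior)
        inc[act_slots] = sign * _spread(c, active, rng)
        return inc
    raise ValueError(traj.shape)


def _spread(total: int, slots: int, rng: np.random.Generator) -> np.ndarray:
    """Spread ``total`` over ``slots`` steps, each >= 1, as evenly as possible."""
    if total < slots:
        raise ValueError(
            f"cannot spread {total} change pixels over {slots} steps with >=1 each"
        )
    base = np.full(slots, total // slots, dtype=int)
    extra = rng.choice(slots, size=total % slots, replace=False)
    base[extra] += 1
    return base


def _convert(
    grid: np.ndarray,
    from_class: int,
    to_class: int,
    n: int,
    rng: np.random.Generator,
) -> None:
    """Convert n pixels of from_class to to_class, in place.

    Pixels Queen-adjacent to the destination class are converted first
    (interface growth); if the interface is exhausted, remaining conversions
    fall on random pixels of the source class.
    """
    if n == 0:
        return
    src = grid == from_class
    if src.sum() < n:
        raise ValueError(
            f"infeasible conversion: need {n} pixels of class {from_class}, "
            f"have {int(src.sum())}"
        )
    remaining = n
    dst_adj = _true_neighbor_counts(grid == to_class) > 0
    interface = np.flatnonzero((src & dst_adj).ravel())
    take = min(remaining, interface.size)
    if take:
        chosen = rng.choice(interface, size=take, replace=False)
        grid.ravel()[chosen] = to_class
        remaining -= take
    while remaining:
        # regrow interface after the previous wave of conversions
        src = grid == from_class
        dst_adj = _true_neighbor_counts(grid == to_class) > 0
        pool = np.flatnonzero((src & dst_adj).ravel())
        if pool.size == 0:
            pool = np.flatnonzero(src.ravel())
        chosen = rng.choice(pool, size=min(remaining, pool.size), replace=False)
        grid.ravel()[chosen] = to_class
        remaining -= chosen.size


def generate_lc_series(spec: CellSpec) -> LCSeries:
    """Generate one cell's annual grids following the spec exactly.

    Year 0 holds ``initial_transition_amount`` transition pixels (arranged
    per ``target_lci`` when set) with forest elsewhere, minus any requested
    background pixels.  The forest-pixel count then follows the trajectory
    spec exactly, through forest<->transition conversions only.
    """
    seed = 0 if spec.seed is None else spec.seed
    rng = np.random.default_rng(seed)
    rows, cols = spec.cell_rows, spec.cell_cols
    n = rows * cols
    k0 = spec.initial_transition_amount

    tmask = arrange_binary(
        k0, rows, cols, target_lci=spec.target_lci, seed=seed
    )
    grid = np.full((rows, cols), spec.forest_class, dtype=np.int16)
    grid[tmask] = spec.transition_class
    if spec.background_amount:
        if not spec.background_classes:
            raise ValueError("background_amount set without background_classes")
        free = np.flatnonzero((grid == spec.forest_class).ravel())
        if free.size < spec.background_amount:
            raise ValueError("not enough forest pixels for background classes")
        chosen = rng.choice(free, size=spec.background_amount, replace=False)
        labels = rng.choice(spec.background_classes, size=chosen.size)
        grid.ravel()[chosen] = labels

    traj = spec.trajectory
    inc = _step_increments(traj, rng)
    # feasibility: track forest/transition balances through the interval
    forest0 = int((grid == spec.forest_class).sum())
    f, t = forest0, k0
    for d in inc:
        f += d
        t -= d
        if f < 0 or t < 0:
            raise ValueError("infeasible trajectory: class count would go negative")

    out = np.empty((spec.n_years, rows, cols), dtype=np.int16)
    out[: traj.start_step + 1] = grid
    cur = grid.copy()
    for i, d in enumerate(inc):
        if d < 0:  # forest loss
            _convert(cur, spec.forest_class, spec.transition_class, -int(d), rng)
        elif d > 0:  # forest gain
            _convert(cur, spec.transition_class, spec.forest_class, int(d), rng)
        out[traj.start_step + 1 + i] = cur
    out[traj.start_step + 1 + len(inc):] = cur
    cid = spec.cell_id or "cell"
    return LCSeries(data=out, cell_id=cid)


def generate_mosaic(cell_specs: list[CellSpec], seed: int = 0) -> dict[str, LCSeries]:
    """One LCSeries per spec, keyed by cell id; reproducible given seed.

    Specs without an explicit seed get one derived from ``seed`` and their
    position; specs without an id are named ``cell_0000``-style.
    """
    if not cell_specs:
        raise ValueError("empty spec list")
    out: dict[str, LCSeries] = {}
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(cell_specs))
    for i, spec in enumerate(cell_specs):
        cid = spec.cell_id or f"cell_{i:04d}"
        if cid in out:
            raise ValueError(f"duplicate cell identifier {cid!r}")
        eff = spec if spec.cell_id == cid else _replace(spec, cell_id=cid)
        if eff.seed is None:
            derived = int(children[i].generate_state(1)[0] % (2**31))
            eff = _replace(eff, seed=derived)
        out[cid] = generate_lc_series(eff)
    return out


def _replace(spec: CellSpec, **kw) -> CellSpec:
    from dataclasses import replace

    return replace(spec, **kw)


def apply_misclassification(
    series: LCSeries,
    rate: float,
    seed: int = 0,
    classes: tuple | None = None,
    temporal_mode: str = "independent",
) -> LCSeries:
    """Perturb labels with symmetric misclassification noise at ``rate``.

    ``independent``: every pixel-year is independently relabelled, with
    probability ``rate``, to a uniformly chosen *different* category.
    ``persistent``: one seeded error field is drawn and applied to every
    year — an affected pixel reports a fixed wrong label for the whole
    series, emulating the temporal persistence of classification errors in
    products built from a baseline map plus change detection.
    """
    if not 0 <= rate <= 1:
        raise ValueError("rate outside [0, 1]")
    if temporal_mode not in ("independent", "persistent"):
        raise ValueError(f"unknown temporal_mode {temporal_mode!r}")
    rng = np.random.default_rng(seed)
    data = series.data.copy()
    cls = np.array(classes if classes is not None else sorted(CATEGORY_CODES.values()))
    if temporal_mode == "independent":
        flips = rng.random(data.shape) < rate
        if flips.any():
            orig = data[flips]
            # uniformly among the other len(cls)-1 categories
            offset = rng.integers(1, len(cls), size=orig.size)
            pos = np.searchsorted(cls, orig)
            data[flips] = cls[(pos + offset) % len(cls)]
    else:
        field_flips = rng.random(data.shape[1:]) < rate
        if field_flips.any():
            orig0 = data[0][field_flips]
            offset = rng.integers(1, len(cls), size=orig0.size)
            pos = np.searchsorted(cls, orig0)
            wrong = cls[(pos + offset) % len(cls)]
            for y in range(data.shape[0]):
                data[y][field_flips] = wrong
    return LCSeries(data=data, cell_id=series.cell_id, years=series.years.copy())


def random_cell_specs(
    n: int,
    seed: int = 0,
    n_years: int = 29,
    rows: int = 18,
    cols: int = 18,
    directions: tuple = ("loss", "gain", "non_persistent"),
    transition_classes: tuple | None = None,
) -> list[CellSpec]:
    """Random but always-feasible cell specs, for tests and simulations."""
    from .categories import CATEGORY_ORDER

    rng = np.random.default_rng(seed)
    if transition_classes is None:
        transition_classes = tuple(
            CATEGORY_CODES[c] for c in CATEGORY_ORDER if c != "forest"
        )
    ncell = rows * cols
    specs = []
    for i in range(n):
        direction = directions[rng.integers(len(directions))]
        if direction == "non_persistent":
            shape = "mixed"
            duration = int(rng.integers(2, n_years - 1))
        else:
            shape = ("gradual", "abrupt", "plateaued")[rng.integers(3)]
            duration = 1 if shape == "abrupt" else int(rng.integers(2, n_years - 1))
        start = int(rng.integers(0, n_years - duration))
        k0 = int(rng.integers(ncell // 8, ncell // 2))
        max_change = min(ncell - k0 - 1, k0 - 1, ncell // 3)
        lo = max(duration, 17)
        change = int(rng.integers(lo, max(lo + 1, max_change)))
        specs.append(
            CellSpec(
                n_years=n_years,
                cell_rows=rows,
                cell_cols=cols,
                transition_class=int(
                    transition_classes[rng.integers(len(transition_classes))]
                ),
                initial_transition_amount=k0,
                trajectory=TrajectorySpec(
                    direction=direction,
                    change_pixels=change,
                    start_step=start,
                    duration_years=duration,
                    shape=shape,
                ),
                seed=int(rng.integers(2**31)),
                cell_id=f"cell_{i:04d}",
            )
        )
    return specs
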