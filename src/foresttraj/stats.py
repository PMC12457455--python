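"""Group summaries by transition land cover and non-parametric effect sizes.

Per-group summaries follow the schema of the study's summary table (n, Q1,
median, mean, Q3, SD, and the group mean minus the pooled mean over all
groups).  Distributional overlap between groups is measured with Cliff's
delta, d = P(x > y) - P(x < y), with the consistent asymptotic variance and
the asymmetric confidence interval of Cliff (1993/1996); ties contribute
zero.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["GroupSummary", "EffectSize", "summarize_groups", "cliffs_delta"]


@dataclass(frozen=True)
class GroupSummary:
    group: object
    n: int
    q1: float
    median: float
    mean: float
    q3: float
    sd: float
    mean_diff: float


@dataclass(frozen=True)
class EffectSize:
    delta: float
    ci_low: float
    ci_high: float
    n_x: int
    n_y: int


def summarize_groups(values, groups) -> list[GroupSummary]:
    """One summary per group; mean_diff is against the pooled mean.

    Quantiles use linear interpolation; SD is the sample SD (ddof = 1), 0
    for single-value groups.  Empty groups are dropped with a warning.
    """
    s = pd.Series(np.asarray(values, dtype=float))
    g = pd.Series(list(groups))
    if len(s) != len(g) or len(s) == 0:
        raise ValueError("values and groups must be equal-length and non-empty")
    global_mean = s.mean()
    out = []
    for label, vals in s.groupby(g.values):
        if len(vals) == 0:  # pragma: no cover - groupby drops empties
            warnings.warn(f"empty group {label!r} omitted")
            continue
        out.append(
            GroupSummary(
                group=label,
                n=int(len(vals)),
                q1=float(vals.quantile(0.25)),
                median=float(vals.median()),
                mean=float(vals.mean()),
                q3=float(vals.quantile(0.75)),
                sd=float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                mean_diff=float(vals.mean() - global_mean),
            )
        )
    return out


def summaries_frame(summaries: list[GroupSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in summaries])


def cliffs_delta(x, y, confidence: float = 0.95) -> EffectSize:
    """Cliff's delta of x over y with an asymptotic confidence interval.

    d = (#{x_i > y_j} - #{x_i < y_j}) / (n_x n_y).  The variance is the
    consistent estimate from the row/column dominance means; the CI uses
    Cliff's asymmetric transformation, which keeps the bounds inside
    [-1, 1] and collapses toward the point estimate when |d| = 1.
    O(n log n) via sorting; no pairwise matrix is formed.
    """
    x = np.sort(np.asarray(x, dtype=float))
    y = np.sort(np.asarray(y, dtype=float))
    nx, ny = x.size, y.size
    if nx == 0 or ny == 0:
        raise ValueError("both samples must be non-empty")

    # row dominance d_i. = (#y < x_i - #y > x_i)/ny, columns symmetric
    lt = np.searchsorted(y, x, side="left")
    gt = ny - np.searchsorted(y, x, side="right")
    d_i = (lt - gt) / ny
    lt2 = np.searchsorted(x, y, side="left")
    gt2 = nx - np.searchsorted(x, y, side="right")
    d_j = (gt2 - lt2) / nx
    d = float(d_i.mean())

    # Sum over all pairs of (d_ij - d)^2, using d_ij in {-1, 0, 1}:
    ties = int(np.sum(np.searchsorted(y, x, "right") - np.searchsorted(y, x, "left")))
    n_pairs = nx * ny
    ss_ij = (n_pairs - ties) - n_pairs * d * d

    if nx > 1 and ny > 1:
        var = (
            ny**2 * np.sum((d_i - d) ** 2)
            + nx**2 * np.sum((d_j - d) ** 2)
            - ss_ij
        ) / (n_pairs * (nx - 1) * (ny - 1))
        var = max(var, 0.0)
    else:
        var = (1 - d * d) / max(n_pairs - 1, 1)

    z = sps.norm.ppf(0.5 + confidence / 2)
    if var == 0.0:
        lo = hi = d
    else:
        s2 = z * z * var
        root = np.sqrt(1 - 2 * d * d + d**4 + s2)
        denom = 1 - d * d + s2
        lo = (d - d**3 - z * np.sqrt(var) * root) / denom
        hi = (d - d**3 + z * np.sqrt(var) * root) / denom
    lo, hi = float(np.clip(lo, -1, 1)), float(np.clip(hi, -1, 1))
    return EffectSize(delta=d, ci_low=min(lo, d), ci_high=max(hi, d), n_x=nx, n_y=ny)


def pairwise_cliffs_delta(values, groups, confidence: float = 0.95) -> pd.DataFrame:
    """Cliff's delta for every ordered pair of distinct group labels."""
    s = pd.Series(np.asarray(values, dtype=float))
    g = pd.Series(list(groups))
    labels = sorted(g.unique())
    rows = []
    for a in labels:
        for b in labels:
            if a == b:
                continue
            e = cliffs_delta(s[g.values == a], s[g.values == b], confidence)
            rows.append(
                {
                    "group_x": a,
                    "group_y": b,
                    "delta": e.delta,
                    "ci_low": e.ci_low,
                    "ci_high": e.ci_high,
                    "n_x": e.n_x,
                    "n_y": e.n_y,
                }
            )
    return pd.DataFrame(rows)
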