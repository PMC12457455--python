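"""End-to-end orchestration: cells -> records -> filters -> statistics -> models.

``analyze_cell`` derives one :class:`CellRecord` from a cell's annual grids:
dominant transition between the first and last maps, interval of forest
change, persistence class, amount and relative rate of change, and initial
conditions (amount and LCI of the transition LC at the interval start).
``run_pipeline`` maps this over a mosaic, applies the exclusion filters,
and emits per-cell records, per-transition-LC group summaries, pairwise
Cliff's deltas, smooth-effect model summaries and a reproducibility
manifest.  Identical configuration and seeds give identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .categories import CODE_NAMES, FOREST
from .series import LCSeries
from .smooth import fit_smooth, summarize_fit
from .stats import pairwise_cliffs_delta, summaries_frame, summarize_groups
from .trajectory import (
    CellRecord,
    ForestSeries,
    amount_of_change,
    apply_filters,
    change_interval,
    change_pixels,
    classify_trajectory,
    initial_state,
    rate_of_change,
    scale_min_change,
)
from .transitions import dominant_transition, transition_matrix

__all__ = ["RunConfig", "analyze_cell", "run_pipeline", "records_frame", "fit_effect_models"]


def analyze_cell(series: LCSeries, forest_class: int = FOREST) -> CellRecord:
    """Derive all per-cell quantities from one annual categorical series."""
    rec = CellRecord(cell_id=series.cell_id)
    m = transition_matrix(series.data[0], series.data[-1])
    dom = dominant_transition(m, forest_class=forest_class)
    if dom is not None:
        rec.from_category = dom.from_category
        rec.to_category = dom.to_category
        rec.certainty = dom.certainty
        rec.involves_forest = dom.involves_forest
        rec.transition_lc = dom.transition_lc
        rec.tie = dom.tie

    fs = ForestSeries.from_series(series, forest_class)
    interval = change_interval(fs)
    rec.trajectory_class = classify_trajectory(fs, interval)
    if interval is not None:
        rec.interval_start = interval.start
        rec.interval_end = interval.end
        rec.duration = interval.duration
        rec.amount_of_change = amount_of_change(fs, interval)
        rec.change_pixels = change_pixels(fs, interval)
        rec.rate_of_change = rate_of_change(interval)
        if rec.transition_lc is not None:
            amount, lci_val = initial_state(series, interval, rec.transition_lc)
            rec.initial_transition_amount = amount
            rec.initial_lci = lci_val
    return rec


def records_frame(records: list[CellRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        d = {k: v for k, v in r.__dict__.items() if k != "filter_flags"}
        d["transition_lc_name"] = CODE_NAMES.get(r.transition_lc, None)
        d["filter_flags"] = ";".join(sorted(r.filter_flags))
        d["retained"] = r.retained
        rows.append(d)
    return pd.DataFrame(rows)


def fit_effect_models(
    df: pd.DataFrame,
    basis_dim: int = 4,
    grid_n: int = 200,
    min_obs: int = 10,
    lci_interpretation_cap: float = 0.6,
) -> pd.DataFrame:
    """One smooth model per (direction, transition LC, predictor, response).

    ``df`` holds retained records.  Responses are the amount and relative
    rate of forest change; predictors are the initial amount and initial
    LCI of the transition LC.  Groups with fewer than ``min_obs`` cells or a
    near-constant predictor are skipped.  For LCI predictors the share of
    observations above the interpretation cap is reported as a flag column;
    the cap never constrains the fit.
    """
    rows = []
    for (direction, lc), grp in df.groupby(["trajectory_class", "transition_lc_name"]):
        for predictor in ("initial_transition_amount", "initial_lci"):
            for response in ("amount_of_change", "rate_of_change"):
                sub = grp[[predictor, response]].dropna()
                if len(sub) < min_obs or sub[predictor].nunique() < basis_dim:
                    continue
                fit = fit_smooth(
                    sub[predictor].values,
                    sub[response].values,
                    basis_dim=basis_dim,
                    predictor=predictor,
                    response=response,
                )
                s = summarize_fit(fit, grid_n=grid_n)
                share_above = float("nan")
                if predictor == "initial_lci":
                    share_above = float((sub[predictor] > lci_interpretation_cap).mean())
                rows.append(
                    {
                        "direction": direction,
                        "transition_lc": lc,
                        "predictor": predictor,
                        "response": response,
                        "n": len(sub),
                        "edf": fit.edf,
                        "null_dev_prop": fit.null_dev_prop,
                        "argmax_x": s.argmax_x,
                        "argmin_x": s.argmin_x,
                        "mean_rate": s.mean_rate,
                        "mean_abs_rate": s.mean_abs_rate,
                        "share_above_lci_cap": share_above,
                    }
                )
    return pd.DataFrame(rows)


@dataclass
class RunConfig:
    """Configuration of one pipeline run (YAML-loadable)."""

    output_dir: str = "results/run"
    input_netcdf: str | None = None  # mosaic file; None -> synthetic
    synthetic: dict = field(default_factory=dict)  # kwargs for random_cell_specs
    cell_pixels: int = 18
    min_change_pixels: int | None = None  # None -> 17 scaled to cell size
    basis_dim: int = 4
    grid_n: int = 200
    misclassification_rate: float = 0.0
    misclassification_mode: str = "independent"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def run_pipeline(cfg: RunConfig, mosaic: dict[str, LCSeries] | None = None) -> dict:
    """Run the full analysis; returns the manifest and writes output tables.

    Cells come from (in order of precedence) the ``mosaic`` argument, the
    configured input NetCDF, or the synthetic generator.  Outputs under
    ``cfg.output_dir``: records.csv, group_summaries.csv, cliffs_delta.csv,
    smooth_models.csv, ua_bounds.csv, manifest.json.
    """
    from .configuration import bounds_table
    from .io import read_mosaic_netcdf
    from .synthetic import apply_misclassification, generate_mosaic, random_cell_specs

    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    if mosaic is None:
        if cfg.input_netcdf:
            mosaic = read_mosaic_netcdf(cfg.input_netcdf)
        else:
            syn = dict(cfg.synthetic)
            n = syn.pop("n", 60)
            specs = random_cell_specs(n, seed=cfg.seed, **syn)
            mosaic = generate_mosaic(specs, seed=cfg.seed)
    if cfg.misclassification_rate > 0:
        mosaic = {
            cid: apply_misclassification(
                s,
                cfg.misclassification_rate,
                seed=cfg.seed + i,
                temporal_mode=cfg.misclassification_mode,
            )
            for i, (cid, s) in enumerate(mosaic.items())
        }

    records = [analyze_cell(s) for s in mosaic.values()]
    sizes = {s.cell_size for s in mosaic.values()}
    cell_size = sizes.pop() if len(sizes) == 1 else 324
    threshold = (
        cfg.min_change_pixels
        if cfg.min_change_pixels is not None
        else scale_min_change(cell_size)
    )
    retained, excluded = apply_filters(records, min_change_pixels=threshold)

    df = records_frame(records)
    df.to_csv(out / "records.csv", index=False)

    reason_counts: dict[str, int] = {}
    for r in excluded:
        for flag in r.filter_flags:
            reason_counts[flag] = reason_counts.get(flag, 0) + 1

    kept = df[df.retained]
    warnings_list = []
    if len(kept) == 0:
        warnings_list.append("no cells retained after filtering; statistics skipped")
        summaries = pd.DataFrame()
        deltas = pd.DataFrame()
        models = pd.DataFrame()
    else:
        parts = []
        for direction, sub in kept.groupby("trajectory_class"):
            for response in ("amount_of_change", "rate_of_change"):
                sf = summaries_frame(
                    summarize_groups(sub[response], sub["transition_lc_name"])
                )
                sf.insert(0, "response", response)
                sf.insert(0, "direction", direction)
                parts.append(sf)
        summaries = pd.concat(parts, ignore_index=True)
        dparts = []
        for direction, sub in kept.groupby("trajectory_class"):
            if sub["transition_lc_name"].nunique() < 2:
                continue
            for response in ("amount_of_change", "rate_of_change"):
                dd = pairwise_cliffs_delta(sub[response], sub["transition_lc_name"])
                dd.insert(0, "response", response)
                dd.insert(0, "direction", direction)
                dparts.append(dd)
        deltas = pd.concat(dparts, ignore_index=True) if dparts else pd.DataFrame()
        models = fit_effect_models(kept, basis_dim=cfg.basis_dim, grid_n=cfg.grid_n)

    summaries.to_csv(out / "group_summaries.csv", index=False)
    deltas.to_csv(out / "cliffs_delta.csv", index=False)
    models.to_csv(out / "smooth_models.csv", index=False)
    rows = cols = int(round(cell_size**0.5))
    bounds_table(rows, cols).to_csv(out / "ua_bounds.csv", index=False)

    cfg_json = json.dumps(cfg.to_dict(), sort_keys=True)
    manifest = {
        "config": cfg.to_dict(),
        "config_hash": hashlib.sha256(cfg_json.encode()).hexdigest()[:16],
        "version": __version__,
        "seed": cfg.seed,
        "n_cells": len(records),
        "n_retained": len(retained),
        "n_excluded": len(excluded),
        "excluded_by_reason": dict(sorted(reason_counts.items())),
        "class_counts": df["trajectory_class"].value_counts().to_dict(),
        "min_change_pixels": threshold,
        "warnings": warnings_list,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
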