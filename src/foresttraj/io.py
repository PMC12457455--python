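"""Reading, reclassifying and tessellating categorical land-cover stacks.

Input stacks are annual categorical rasters, either one GeoTIFF per year or
a single NetCDF cube with dimensions (year, row, col).  Maps are first
reclassified to the eight aggregated IPCC categories (the level at which
categorical change detection is considered reliable; sparse vegetation folds
into bare), then tessellated into mutually exclusive square analysis cells
(default 18x18 source pixels, the 3 arc-minute cell of a 300 m product;
36x36 and 180x180 give the 6 and 30 arc-minute variants — scale is a
parameter, not new code).

Conventions: row-major, 0-based pixel indices; a cell's origin is its
north-west corner.  Any cell touching nodata in any year, or truncated at
the raster edge, is flagged incomplete and excluded downstream (the
conservative reading of the equal-size filter).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .categories import CATEGORY_CODES, DEFAULT_CCI_RECLASS
from .series import LCSeries

__all__ = [
    "ReclassTable",
    "CellGridIndex",
    "reclassify",
    "tessellate",
    "read_geotiff_stack",
    "read_netcdf_stack",
    "write_mosaic_netcdf",
    "read_mosaic_netcdf",
]


@dataclass(frozen=True)
class ReclassTable:
    """Mapping from source class codes to IPCC category codes."""

    mapping: dict

    def __post_init__(self):
        bad = [c for c in self.mapping.values() if c not in CATEGORY_CODES.values()]
        if bad:
            raise ValueError(f"mapped values are not IPCC category codes: {sorted(set(bad))}")

    @classmethod
    def default_cci(cls) -> "ReclassTable":
        """The 22-class CCI-LC legend aggregated to 8 IPCC categories."""
        return cls(mapping=dict(DEFAULT_CCI_RECLASS))

    @classmethod
    def identity(cls) -> "ReclassTable":
        return cls(mapping={c: c for c in CATEGORY_CODES.values()})

    @classmethod
    def from_csv(cls, path) -> "ReclassTable":
        """CSV with columns ``code`` and ``category`` (category names)."""
        df = pd.read_csv(path)
        mapping = {
            int(row.code): CATEGORY_CODES[str(row.category).strip().lower()]
            for row in df.itertuples()
        }
        return cls(mapping=mapping)


@dataclass(frozen=True)
class CellGridIndex:
    """Location of one analysis cell within the source raster."""

    cell_id: str
    row_off: int
    col_off: int
    cell_rows: int
    cell_cols: int
    bounds: tuple | None = None  # (lon_min, lat_min, lon_max, lat_max), degrees
    complete: bool = True
    reason: str | None = None


def reclassify(grid: np.ndarray, table: ReclassTable) -> np.ndarray:
    """Map every source code through the table; unmapped codes are an error."""
    g = np.asarray(grid)
    codes = np.unique(g)
    unmapped = [int(c) for c in codes if int(c) not in table.mapping]
    if unmapped:
        raise ValueError(f"unmapped class codes: {unmapped}")
    lut = np.zeros(int(codes.max()) + 1, dtype=np.int16)
    for src, dst in table.mapping.items():
        if src <= codes.max():
            lut[src] = dst
    return lut[g]


def tessellate(
    stack: np.ndarray,
    cell_pixels: int = 18,
    nodata: int | None = None,
    transform: tuple | None = None,
) -> list[tuple[CellGridIndex, LCSeries | None]]:
    """Cut a (years, rows, cols) stack into cell_pixels-square cells.

    Every complete cell is emitted once with its series; cells truncated at
    the raster boundary or containing nodata in any year are emitted with a
    None series and an exclusion reason.  ``transform`` is
    (lon_origin, lat_origin, dlon, dlat) of the raster's north-west corner
    (dlat negative for north-up rasters) and, when given, fills geographic
    cell bounds.
    """
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ValueError("stack must be (years, rows, cols)")
    if cell_pixels < 2:
        raise ValueError("cell_pixels must be >= 2")
    _, nrows, ncols = stack.shape
    out = []
    cell = 0
    for r0 in range(0, nrows, cell_pixels):
        for c0 in range(0, ncols, cell_pixels):
            r1, c1 = r0 + cell_pixels, c0 + cell_pixels
            cid = f"cell_r{r0:05d}_c{c0:05d}"
            bounds = _cell_bounds(transform, r0, c0, min(r1, nrows), min(c1, ncols))
            if r1 > nrows or c1 > ncols:
                out.append(
                    (
                        CellGridIndex(cid, r0, c0, min(r1, nrows) - r0,
                                      min(c1, ncols) - c0, bounds,
                                      complete=False, reason="incomplete"),
                        None,
                    )
                )
                continue
            block = stack[:, r0:r1, c0:c1]
            if nodata is not None and (block == nodata).any():
                out.append(
                    (
                        CellGridIndex(cid, r0, c0, cell_pixels, cell_pixels,
                                      bounds, complete=False, reason="incomplete"),
                        None,
                    )
                )
                continue
            idx = CellGridIndex(cid, r0, c0, cell_pixels, cell_pixels, bounds)
            out.append((idx, LCSeries(data=block.copy(), cell_id=cid)))
            cell += 1
    return out


def _cell_bounds(transform, r0, c0, r1, c1):
    if transform is None:
        return None
    lon0, lat0, dlon, dlat = transform
    xs = sorted([lon0 + c0 * dlon, lon0 + c1 * dlon])
    ys = sorted([lat0 + r0 * dlat, lat0 + r1 * dlat])
    return (xs[0], ys[0], xs[1], ys[1])


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_geotiff_stack(paths: list) -> np.ndarray:
    """Stack one single-band categorical GeoTIFF per year into (years, r, c)."""
    import tifffile

    grids = []
    for p in paths:
        arr = np.asarray(tifffile.imread(str(p)))
        if arr.ndim != 2:
            raise ValueError(f"{p}: expected a single-band raster")
        grids.append(arr)
    shapes = {g.shape for g in grids}
    if len(shapes) != 1:
        raise ValueError(f"stack years disagree in shape: {sorted(shapes)}")
    return np.stack(grids)


def read_netcdf_stack(path, var: str = "lc") -> np.ndarray:
    with xr.open_dataset(path, engine="scipy") as ds:
        return ds[var].transpose("year", "row", "col").values


def write_mosaic_netcdf(mosaic: dict[str, LCSeries], path) -> None:
    """Write a mosaic of equally shaped cell series as one NetCDF file.

    Dimensions (cell, year, row, col) with the cell ids as a coordinate;
    integer class codes.  NetCDF3 (scipy engine), readable anywhere.
    """
    if not mosaic:
        raise ValueError("empty mosaic")
    ids = list(mosaic)
    first = mosaic[ids[0]]
    data = np.stack([mosaic[i].data for i in ids]).astype(np.int16)
    ds = xr.Dataset(
        {"lc": (("cell", "year", "row", "col"), data)},
        coords={
            "cell": np.arange(len(ids)),
            "year": np.asarray(first.years),
        },
        attrs={"cell_ids": ",".join(ids)},
    )
    ds.to_netcdf(str(path), engine="scipy")


def read_mosaic_netcdf(path) -> dict[str, LCSeries]:
    with xr.open_dataset(str(path), engine="scipy") as ds:
        ids = str(ds.attrs["cell_ids"]).split(",")
        years = ds["year"].values
        data = ds["lc"].values
    return {
        cid: LCSeries(data=data[i], cell_id=cid, years=years.copy())
        for i, cid in enumerate(ids)
    }


def write_metadata_csv(specs, path) -> None:
    """Per-cell generator metadata as CSV (one row per cell spec)."""
    rows = []
    for s in specs:
        t = s.trajectory
        rows.append(
            {
                "cell_id": s.cell_id,
                "n_years": s.n_years,
                "cell_rows": s.cell_rows,
                "cell_cols": s.cell_cols,
                "forest_class": s.forest_class,
                "transition_class": s.transition_class,
                "initial_transition_amount": s.initial_transition_amount,
                "target_lci": s.target_lci,
                "direction": t.direction,
                "change_pixels": t.change_pixels,
                "start_step": t.start_step,
                "duration_years": t.duration_years,
                "shape": t.shape,
                "seed": s.seed,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
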