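"""Input/output of survey tables and categorical land-cover rasters.

Rasters are exchanged as ESRI ASCII grids with integer category codes;
``NODATA_value 0`` marks cells outside the buffer.  Survey records, species
group tags and richness tables are plain CSV read into pandas frames.

The central operation here is :func:`richness`: pooling survey records into
distinct-species counts per (site, period, habitat group), with aquatic
("excluded") species dropped from every column.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import ndimage

from .config import (
    DEFAULT_CATEGORY_MAP,
    DEFAULT_PERIOD_WINDOWS,
    RESPONSE_GROUPS,
    Category,
)

__all__ = [
    "LandscapeMosaic",
    "MosaicFormatError",
    "read_mosaic",
    "write_mosaic",
    "read_records",
    "read_groups",
    "richness",
]

VALID_GROUPS = ("woodland", "farmland", "steppe", "excluded")


class MosaicFormatError(ValueError):
    """Raised for malformed rasters or unknown category codes."""


@dataclass
class LandscapeMosaic:
    """A categorical raster for one site and period.

    Parameters
    ----------
    grid
        2-D integer array of category codes; 0 marks cells outside the buffer.
    cell_size
        Cell side length in metres.
    category_map
        Mapping from nonzero code to :class:`~farmscape.config.Category`.
    """

    grid: np.ndarray
    cell_size: float
    category_map: Mapping[int, Category] = field(default_factory=lambda: DEFAULT_CATEGORY_MAP)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 2:
            raise MosaicFormatError(f"grid must be 2-D, got shape {self.grid.shape}")
        if not np.issubdtype(self.grid.dtype, np.integer):
            if np.any(self.grid != np.round(self.grid)):
                raise MosaicFormatError("raster values must be integer category codes")
            self.grid = self.grid.astype(np.int64)
        if self.cell_size <= 0:
            raise MosaicFormatError("cell_size must be positive")
        unknown = set(np.unique(self.grid)) - set(self.category_map) - {0}
        if unknown:
            raise MosaicFormatError(f"unknown category codes in raster: {sorted(unknown)}")

    @property
    def buffer_mask(self) -> np.ndarray:
        return self.grid != 0

    @property
    def n_buffer_cells(self) -> int:
        return int(self.buffer_mask.sum())

    @property
    def buffer_area_ha(self) -> float:
        return self.n_buffer_cells * self.cell_size**2 / 1e4

    def buffer_is_connected(self) -> bool:
        """True if the nonzero (inside-buffer) region is a single 8-connected blob."""
        mask = self.buffer_mask
        if not mask.any():
            return False
        _, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
        return n == 1


def read_mosaic(
    path: str | Path,
    category_map: Mapping[int, Category] | None = None,
    *,
    require_connected: bool = False,
) -> LandscapeMosaic:
    """Read an ESRI ASCII grid into a :class:`LandscapeMosaic`.

    The header must declare ``ncols, nrows, xllcorner, yllcorner, cellsize``
    and optionally ``NODATA_value`` (treated as outside-buffer and remapped
    to 0).  Unknown category codes raise :class:`MosaicFormatError`.
    """
    category_map = DEFAULT_CATEGORY_MAP if category_map is None else category_map
    text = Path(path).read_text()
    lines = text.splitlines()
    header: dict[str, float] = {}
    body_start = 0
    for i, line in enumerate(lines):
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in (
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        ):
            header[parts[0].lower()] = float(parts[1])
            body_start = i + 1
        else:
            break
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise MosaicFormatError(f"missing ESRI ASCII header field {key!r} in {path}")
    raw = np.loadtxt(io.StringIO("\n".join(lines[body_start:])), ndmin=2)
    if np.any(raw != np.round(raw)):
        raise MosaicFormatError(f"non-integer raster values in {path}")
    grid = raw.astype(np.int64)
    if grid.shape != (int(header["nrows"]), int(header["ncols"])):
        raise MosaicFormatError(
            f"grid shape {grid.shape} does not match header "
            f"({int(header['nrows'])}, {int(header['ncols'])})"
        )
    nodata = int(header.get("nodata_value", 0))
    if nodata != 0:
        grid[grid == nodata] = 0
    mosaic = LandscapeMosaic(grid, header["cellsize"], category_map)
    if require_connected and not mosaic.buffer_is_connected():
        raise MosaicFormatError(f"buffer region in {path} is not connected")
    return mosaic


def write_mosaic(mosaic: LandscapeMosaic, path: str | Path) -> None:
    """Write an ESRI ASCII grid with a fixed header order.

    The header order and integer formatting are stable, so
    ``write(read(f))`` is byte-identical for files produced by this writer.
    """
    grid = mosaic.grid
    lines = [
        f"ncols {grid.shape[1]}",
        f"nrows {grid.shape[0]}",
        "xllcorner 0",
        "yllcorner 0",
        f"cellsize {mosaic.cell_size:g}",
        "NODATA_value 0",
    ]
    lines += [" ".join(str(int(v)) for v in row) for row in grid]
    Path(path).write_text("\n".join(lines) + "\n")


def read_records(path: str | Path) -> pd.DataFrame:
    """Read survey records CSV with columns ``site_id, year, species``."""
    df = pd.read_csv(path, dtype={"site_id": str, "species": str})
    missing = {"site_id", "year", "species"} - set(df.columns)
    if missing:
        raise ValueError(f"records file missing columns: {sorted(missing)}")
    if df["species"].isna().any() or (df["species"].str.len() == 0).any():
        raise ValueError("records contain empty species identifiers")
    return df


def read_groups(path: str | Path) -> pd.DataFrame:
    """Read the species -> habitat-group table (columns ``species, group``)."""
    df = pd.read_csv(path, dtype=str)
    missing = {"species", "group"} - set(df.columns)
    if missing:
        raise ValueError(f"group table missing columns: {sorted(missing)}")
    bad = set(df["group"]) - set(VALID_GROUPS)
    if bad:
        raise ValueError(f"unknown habitat groups: {sorted(bad)}; expected {VALID_GROUPS}")
    if df["species"].duplicated().any():
        dups = df.loc[df["species"].duplicated(), "species"].tolist()
        raise ValueError(f"species with multiple group rows: {dups}")
    return df


def _assign_period(years: pd.Series, period_windows: Mapping[str, tuple[int, int]]) -> pd.Series:
    wins = sorted(period_windows.items(), key=lambda kv: kv[1])
    for (n1, (_, b1)), (n2, (a2, _)) in zip(wins, wins[1:]):
        if b1 >= a2:
            raise ValueError(f"period windows {n1!r} and {n2!r} overlap")
    period = pd.Series(pd.NA, index=years.index, dtype=object)
    for name, (lo, hi) in period_windows.items():
        period[years.between(lo, hi)] = name
    return period


def richness(
    records: pd.DataFrame,
    groups: pd.DataFrame,
    period_windows: Mapping[str, tuple[int, int]] | None = None,
    *,
    steppe_in_farmland: bool = True,
) -> pd.DataFrame:
    """Pool survey records into distinct-species counts per site, period and group.

    Records are pooled across the years of each period window.  The ``all``
    column counts every non-excluded species; ``woodland``/``farmland``/
    ``steppe`` count species carrying that tag.  With ``steppe_in_farmland``
    (the default, reflecting steppe birds being open-grassland farmland
    specialists) steppe-tagged species also count toward ``farmland``.

    Returns a long-format frame with columns
    ``site_id, period, group, richness``, one row per (site, period) for each
    of the four groups, richness 0 where no qualifying species was seen.

    Raises
    ------
    ValueError
        If any record's year falls outside every declared window, or a
        surveyed species is missing from the group table.
    """
    period_windows = DEFAULT_PERIOD_WINDOWS if period_windows is None else period_windows
    rec = records.copy()
    rec["period"] = _assign_period(rec["year"], period_windows)
    stray = rec[rec["period"].isna()]
    if len(stray):
        raise ValueError(
            "records outside all period windows: "
            + ", ".join(f"({r.site_id}, {r.year}, {r.species})" for r in stray.head(20).itertuples())
        )
    tag = groups.set_index("species")["group"]
    unknown = set(rec["species"]) - set(tag.index)
    if unknown:
        raise ValueError(f"surveyed species missing from group table: {sorted(unknown)[:20]}")
    rec["group_tag"] = rec["species"].map(tag)
    rec = rec[rec["group_tag"] != "excluded"]

    keys = rec[["site_id", "period"]].drop_duplicates()
    rows = []
    for site_id, period in keys.itertuples(index=False):
        sub = rec[(rec["site_id"] == site_id) & (rec["period"] == period)]
        counts = {
            "all": sub["species"].nunique(),
            "woodland": sub.loc[sub["group_tag"] == "woodland", "species"].nunique(),
            "steppe": sub.loc[sub["group_tag"] == "steppe", "species"].nunique(),
        }
        farm_tags = ("farmland", "steppe") if steppe_in_farmland else ("farmland",)
        counts["farmland"] = sub.loc[sub["group_tag"].isin(farm_tags), "species"].nunique()
        for group in RESPONSE_GROUPS:
            rows.append((site_id, period, group, counts[group]))
    out = pd.DataFrame(rows, columns=["site_id", "period", "group", "richness"])
    return out.sort_values(["site_id", "period", "group"], ignore_index=True)
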