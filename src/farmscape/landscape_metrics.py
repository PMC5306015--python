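"""Buffer-scale landscape metrics on categorical rasters.

Per mosaic and per landscape component (natural / production) this module
computes the three blocks of variables used downstream:

* composition — percent cover of every category relative to the buffer area;
* compositional heterogeneity — number of cover categories present, Shannon
  diversity H = -sum p_i ln p_i (proportions relative to the component's own
  area) and Pielou evenness H / ln(richness);
* configurational heterogeneity — largest patch index (% of buffer area in
  the single largest patch), mean patch size (ha), edge density (m/ha of
  inter-category boundary, buffer border excluded) and mean shape index
  (0.25 P / sqrt(A) in cell units; 1 for a square patch).

Patches are maximal same-category connected components (8-connectivity by
default, as in the reference landscape-metrics software; 4-connectivity
available).  Patch perimeter counts cell edges adjacent to a different
category, to outside-buffer cells or to the grid border.  Absent components
yield 0 for every metric, so the variables are defined for all buffers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import ndimage

from .config import ALL_VARIABLES, NATURAL, PRODUCTION, component_codes
from .survey_io import LandscapeMosaic

__all__ = [
    "Patch",
    "label_patches",
    "composition",
    "compositional_heterogeneity",
    "configurational_heterogeneity",
    "metrics_row",
    "metrics_table",
]

_STRUCT8 = np.ones((3, 3), dtype=int)
_STRUCT4 = ndimage.generate_binary_structure(2, 1)


@dataclass(frozen=True)
class Patch:
    """One contiguous same-category patch."""

    category: int
    cell_count: int
    area_ha: float
    perimeter_m: float
    patch_id: int

    @property
    def perimeter_edges(self) -> int:
        """Perimeter expressed as a count of cell edges."""
        return int(round(self.perimeter_m / (self.area_ha * 1e4 / self.cell_count) ** 0.5))

    @property
    def shape_index(self) -> float:
        """0.25 P / sqrt(A) in cell units; equals 1 for a square patch."""
        return 0.25 * self.perimeter_edges / np.sqrt(self.cell_count)


def _perimeter_edges(patch_mask: np.ndarray, same_category: np.ndarray) -> int:
    """Cell edges of `patch_mask` bordering a different category, NODATA or the grid edge."""
    n = 0
    for axis, side in ((0, 1), (0, -1), (1, 1), (1, -1)):
        neighbour_same = np.zeros_like(same_category)
        src = np.roll(same_category, side, axis=axis)
        neighbour_same[:] = src
        # roll wraps around; the wrapped row/column borders the grid edge
        if axis == 0:
            idx = 0 if side == 1 else -1
            neighbour_same[idx, :] = False
        else:
            idx = 0 if side == 1 else -1
            neighbour_same[:, idx] = False
        n += int(np.sum(patch_mask & ~neighbour_same))
    return n


def label_patches(
    mosaic: LandscapeMosaic,
    component: str,
    connectivity: int = 8,
) -> list[Patch]:
    """Partition a component's cells into maximal connected same-category patches.

    Parameters
    ----------
    component
        ``"natural"`` or ``"production"``.
    connectivity
        8 (default) or 4; controls which diagonal contacts join a patch.

    Returns an empty list when the component has no cells.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    structure = _STRUCT8 if connectivity == 8 else _STRUCT4
    codes = component_codes(mosaic.category_map, component)
    cell_area_ha = mosaic.cell_size**2 / 1e4
    patches: list[Patch] = []
    pid = 0
    for code in codes:
        cat_mask = mosaic.grid == code
        if not cat_mask.any():
            continue
        labels, n = ndimage.label(cat_mask, structure=structure)
        for lab in range(1, n + 1):
            patch_mask = labels == lab
            cells = int(patch_mask.sum())
            edges = _perimeter_edges(patch_mask, cat_mask)
            patches.append(
                Patch(
                    category=int(code),
                    cell_count=cells,
                    area_ha=cells * cell_area_ha,
                    perimeter_m=edges * mosaic.cell_size,
                    patch_id=pid,
                )
            )
            pid += 1
    return patches


def composition(mosaic: LandscapeMosaic) -> dict[int, float]:
    """Percent cover of every declared category relative to the buffer area."""
    total = mosaic.n_buffer_cells
    if total == 0:
        raise ValueError("empty buffer: no nonzero cells")
    return {
        int(code): 100.0 * float(np.sum(mosaic.grid == code)) / total
        for code in mosaic.category_map
    }


def compositional_heterogeneity(mosaic: LandscapeMosaic, component: str) -> dict[str, float]:
    """Cover richness, Shannon diversity (nats) and Pielou evenness of one component.

    Proportions are relative to the component's own area so that a thin
    natural component is described on the same scale as a dominant production
    component.  With a single category H = 0 and evenness is defined as 0;
    an absent component yields 0 for all three.
    """
    codes = component_codes(mosaic.category_map, component)
    counts = np.array([np.sum(mosaic.grid == code) for code in codes], dtype=float)
    counts = counts[counts > 0]
    richness = int(len(counts))
    if richness == 0:
        return {"cover_richness": 0, "cover_diversity": 0.0, "cover_evenness": 0.0}
    p = counts / counts.sum()
    diversity = float(-np.sum(p * np.log(p)))
    evenness = float(diversity / np.log(richness)) if richness > 1 else 0.0
    return {
        "cover_richness": richness,
        "cover_diversity": diversity,
        "cover_evenness": evenness,
    }


def _edge_length_m(mosaic: LandscapeMosaic, codes: Iterable[int]) -> float:
    """Total inter-category boundary length touching the component, in metres.

    Counts each internal 4-adjacent cell pair once when both cells are inside
    the buffer, their categories differ, and at least one belongs to the
    component.  Buffer border and grid border are excluded by construction.
    """
    grid = mosaic.grid
    in_comp = np.isin(grid, list(codes))
    n_edges = 0
    for axis in (0, 1):
        a = grid.take(range(grid.shape[axis] - 1), axis=axis)
        b = grid.take(range(1, grid.shape[axis]), axis=axis)
        ca = in_comp.take(range(grid.shape[axis] - 1), axis=axis)
        cb = in_comp.take(range(1, grid.shape[axis]), axis=axis)
        n_edges += int(np.sum((a != 0) & (b != 0) & (a != b) & (ca | cb)))
    return n_edges * mosaic.cell_size


def configurational_heterogeneity(mosaic: LandscapeMosaic, component: str) -> dict[str, float]:
    """Largest patch index, mean patch size, edge density and mean shape index."""
    patches = label_patches(mosaic, component)
    if not patches:
        return {"lpi": 0.0, "mean_patch_size": 0.0, "edge_density": 0.0, "shape_index": 0.0}
    buffer_ha = mosaic.buffer_area_ha
    areas = np.array([p.area_ha for p in patches])
    codes = component_codes(mosaic.category_map, component)
    return {
        "lpi": float(100.0 * areas.max() / buffer_ha),
        "mean_patch_size": float(areas.mean()),
        "edge_density": _edge_length_m(mosaic, codes) / buffer_ha,
        "shape_index": float(np.mean([p.shape_index for p in patches])),
    }


def metrics_row(mosaic: LandscapeMosaic) -> dict[str, float]:
    """All 24 landscape variables for one mosaic, keyed by canonical names."""
    row: dict[str, float] = {}
    covers = composition(mosaic)
    for code, cat in mosaic.category_map.items():
        row[cat.name] = covers[code]
    for prefix, comp in (("nat", NATURAL), ("prod", PRODUCTION)):
        for key, val in compositional_heterogeneity(mosaic, comp).items():
            row[f"{prefix}_{key}"] = val
        for key, val in configurational_heterogeneity(mosaic, comp).items():
            row[f"{prefix}_{key}"] = val
    return row


def metrics_table(mosaics: Mapping[tuple[str, str], LandscapeMosaic]) -> pd.DataFrame:
    """Metric table over ``{(site_id, period): mosaic}``: one row per site/period."""
    rows = []
    for (site_id, period), mosaic in mosaics.items():
        rows.append({"site_id": site_id, "period": period, **metrics_row(mosaic)})
    df = pd.DataFrame(rows)
    ordered = ["site_id", "period"] + [v for v in ALL_VARIABLES if v in df.columns]
    return df[ordered].sort_values(["site_id", "period"], ignore_index=True)
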