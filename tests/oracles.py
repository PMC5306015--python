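"""Independent brute-force oracles for landscape metrics.

Deliberately naive: explicit flood fill for patches and explicit loops over
cell pairs for edges, sharing no code with the implementation.
"""

from __future__ import annotations

import numpy as np


def flood_fill_patches(grid: np.ndarray, codes, connectivity: int = 8):
    """Partition component cells into patches by stack-based flood fill.

    Returns a list of patches, each a dict with the category, the set of
    cells, and the perimeter in cell edges (edges bordering a different
    category, NODATA or the grid border).
    """
    rows, cols = grid.shape
    if connectivity == 8:
        neigh = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        neigh = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    seen = np.zeros_like(grid, dtype=bool)
    patches = []
    for r in range(rows):
        for c in range(cols):
            code = grid[r, c]
            if code not in codes or seen[r, c]:
                continue
            stack = [(r, c)]
            seen[r, c] = True
            cells = set()
            while stack:
                rr, cc = stack.pop()
                cells.add((rr, cc))
                for dr, dc in neigh:
                    nr, nc = rr + dr, cc + dc
                    if 0 <= nr < rows and 0 <= nc < cols and not seen[nr, nc] and grid[nr, nc] == code:
                        seen[nr, nc] = True
                        stack.append((nr, nc))
            perim = 0
            for rr, cc in cells:
                for dr, dc in [(-1, 0), (1, 0), (0, -1), (0, 1)]:
                    nr, nc = rr + dr, cc + dc
                    if not (0 <= nr < rows and 0 <= nc < cols) or grid[nr, nc] != code:
                        perim += 1
            patches.append({"category": int(code), "cells": cells, "perimeter_edges": perim})
    return patches


def edge_length_edges(grid: np.ndarray, codes) -> int:
    """Internal differing-category 4-adjacencies touching the component, counted once."""
    rows, cols = grid.shape
    n = 0
    for r in range(rows):
        for c in range(cols):
            for dr, dc in [(1, 0), (0, 1)]:
                nr, nc = r + dr, c + dc
                if nr >= rows or nc >= cols:
                    continue
                a, b = grid[r, c], grid[nr, nc]
                if a != 0 and b != 0 and a != b and (a in codes or b in codes):
                    n += 1
    return n


def config_metrics_oracle(grid: np.ndarray, codes, cell_size: float) -> dict:
    """LPI, mean patch size, edge density and mean shape index the slow way."""
    patches = flood_fill_patches(grid, codes)
    cell_ha = cell_size**2 / 1e4
    buffer_ha = int((grid != 0).sum()) * cell_ha
    if not patches:
        return {"lpi": 0.0, "mean_patch_size": 0.0, "edge_density": 0.0, "shape_index": 0.0}
    areas = [len(p["cells"]) * cell_ha for p in patches]
    shapes = [0.25 * p["perimeter_edges"] / np.sqrt(len(p["cells"])) for p in patches]
    return {
        "lpi": 100.0 * max(areas) / buffer_ha,
        "mean_patch_size": float(np.mean(areas)),
        "edge_density": edge_length_edges(grid, codes) * cell_size / buffer_ha,
        "shape_index": float(np.mean(shapes)),
    }
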