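"""Watershed delineation and catchment summaries on raster grids.

Flow routing is deterministic eight-direction (D8): each cell drains to
the steepest-descent neighbour, with drops over diagonals divided by
sqrt(2) times the cell size. Depressions are removed by priority-flood
*filling* (the classic breach alternative gives identical drainage on
the toy grids used here); flats left by filling are resolved by
breadth-first distance to the flat's spill cells.

Conventions
-----------
* neighbour ordering E, SE, S, SW, W, NW, N, NE with direction codes
  1, 2, 4, 8, 16, 32, 64, 128; ties take the first neighbour in order;
* code 0 marks an outlet (edge cell with no lower neighbour);
* grid indices are ``(row, col)`` with row 0 at the top of the map.
"""

from __future__ import annotations

import heapq
from collections import deque
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_dilation

from .rasters import Raster

__all__ = [
    "CatchmentSummary",
    "FlowField",
    "OUTLET_CODE",
    "d8_flow_direction",
    "delineate_watershed",
    "fill_depressions",
    "find_pour_point",
    "flow_accumulation",
    "sum_wwtw_load",
    "summarize_landcover",
]

# neighbour order: E, SE, S, SW, W, NW, N, NE  (row 0 = top, so S is +row)
NEIGHBOR_OFFSETS = ((0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1))
D8_CODES = (1, 2, 4, 8, 16, 32, 64, 128)
OUTLET_CODE = 0
UNDEFINED_CODE = -1
_DIAG = (False, True, False, True, False, True, False, True)

_CODE_TO_OFFSET = dict(zip(D8_CODES, NEIGHBOR_OFFSETS))


@dataclass
class FlowField:
    """D8 direction codes plus cell-count flow accumulation."""

    direction: np.ndarray
    accumulation: np.ndarray


@dataclass
class CatchmentSummary:
    area_km2: float
    forest_prop: float
    urban_prop: float
    wwtw_load_pe: float


def fill_depressions(dem: Raster) -> Raster:
    """Priority-flood depression filling.

    Output elevations are elementwise >= input, every valid cell has a
    non-ascending 8-neighbour path to the grid edge, and the operation
    is idempotent.
    """
    values = dem.values
    valid = dem.mask_valid()
    if not valid.any():
        raise ValueError("DEM contains no valid cells")
    nrows, ncols = values.shape
    filled = np.where(valid, values, np.nan)
    closed = ~valid  # nodata never processed
    heap: list[tuple[float, int, int]] = []

    def is_seed(r: int, c: int) -> bool:
        if r in (0, nrows - 1) or c in (0, ncols - 1):
            return True
        for dr, dc in NEIGHBOR_OFFSETS:
            if not valid[r + dr, c + dc]:
                return True
        return False

    for r in range(nrows):
        for c in range(ncols):
            if valid[r, c] and is_seed(r, c):
                heapq.heappush(heap, (values[r, c], r, c))
                closed[r, c] = True

    while heap:
        elev, r, c = heapq.heappop(heap)
        filled[r, c] = elev
        for dr, dc in NEIGHBOR_OFFSETS:
            nr, nc = r + dr, c + dc
            if 0 <= nr < nrows and 0 <= nc < ncols and not closed[nr, nc]:
                closed[nr, nc] = True
                heapq.heappush(heap, (max(values[nr, nc], elev), nr, nc))

    out = np.where(valid, filled, dem.nodata)
    return dem.copy_with(out)


def d8_flow_direction(dem: Raster) -> np.ndarray:
    """Steepest-descent D8 direction codes for a depression-handled DEM.

    Edge cells (or cells bordering nodata) without a lower neighbour are
    outlets (code 0). Flat cells are pointed across equal elevation
    towards the flat's spill cells, nearer cells first, which reproduces
    distance-to-outlet ordering.
    """
    values = dem.values
    valid = dem.mask_valid()
    nrows, ncols = values.shape
    direction = np.full((nrows, ncols), UNDEFINED_CODE, dtype=int)

    def neighbours(r, c):
        for (dr, dc), code, diag in zip(NEIGHBOR_OFFSETS, D8_CODES, _DIAG):
            nr, nc = r + dr, c + dc
            if 0 <= nr < nrows and 0 <= nc < ncols and valid[nr, nc]:
                yield nr, nc, code, diag
            else:
                yield None, None, code, diag  # off-grid / nodata

    for r in range(nrows):
        for c in range(ncols):
            if not valid[r, c]:
                continue
            best_code, best_slope = None, 0.0
            touches_edge = False
            for nr, nc, code, diag in neighbours(r, c):
                if nr is None:
                    touches_edge = True
                    continue
                drop = values[r, c] - values[nr, nc]
                slope = drop / (np.sqrt(2.0) if diag else 1.0)
                if slope > best_slope:  # strict: ties keep first found
                    best_code, best_slope = code, slope
            if best_code is not None:
                direction[r, c] = best_code
            elif touches_edge:
                direction[r, c] = OUTLET_CODE

    # resolve flats: BFS from already-resolved cells across equal elevation
    queue: deque[tuple[int, int]] = deque()
    for r in range(nrows):
        for c in range(ncols):
            if not valid[r, c] or direction[r, c] != UNDEFINED_CODE:
                continue
            for nr, nc, code, _ in neighbours(r, c):
                if nr is None:
                    continue
                if direction[nr, nc] != UNDEFINED_CODE and values[nr, nc] <= values[r, c]:
                    direction[r, c] = code
                    queue.append((r, c))
                    break
    while queue:
        r, c = queue.popleft()
        for nr, nc, code, _ in neighbours(r, c):
            if nr is None:
                continue
            if direction[nr, nc] == UNDEFINED_CODE and values[nr, nc] == values[r, c]:
                # neighbour drains through (r, c): point it back at us
                direction[nr, nc] = _opposite_code(code)
                queue.append((nr, nc))

    unresolved = valid & (direction == UNDEFINED_CODE)
    if unresolved.any():
        r, c = np.argwhere(unresolved)[0]
        raise ValueError(f"flat interior region with no outlet at cell ({r}, {c})")
    direction[~valid] = UNDEFINED_CODE
    return direction


def _opposite_code(code: int) -> int:
    idx = D8_CODES.index(code)
    return D8_CODES[(idx + 4) % 8]


def downstream_cell(direction: np.ndarray, r: int, c: int) -> tuple[int, int] | None:
    """The cell that ``(r, c)`` drains to, or None for outlets."""
    code = direction[r, c]
    if code in (OUTLET_CODE, UNDEFINED_CODE):
        return None
    dr, dc = _CODE_TO_OFFSET[int(code)]
    return r + dr, c + dc


def flow_accumulation(direction: np.ndarray) -> np.ndarray:
    """Cell counts draining through each cell (each cell counts itself).

    Processes cells in topological order; a cycle in the direction grid
    raises with the index of a cell on the cycle.
    """
    nrows, ncols = direction.shape
    valid = direction != UNDEFINED_CODE
    acc = np.where(valid, 1.0, np.nan)
    indegree = np.zeros((nrows, ncols), dtype=int)
    for r in range(nrows):
        for c in range(ncols):
            if valid[r, c]:
                ds = downstream_cell(direction, r, c)
                if ds is not None:
                    indegree[ds] += 1
    queue = deque(
        (r, c) for r in range(nrows) for c in range(ncols) if valid[r, c] and indegree[r, c] == 0
    )
    processed = 0
    while queue:
        r, c = queue.popleft()
        processed += 1
        ds = downstream_cell(direction, r, c)
        if ds is not None:
            acc[ds] += acc[r, c]
            indegree[ds] -= 1
            if indegree[ds] == 0:
                queue.append(ds)
    if processed < int(valid.sum()):
        leftovers = valid & (indegree > 0)
        r, c = np.argwhere(leftovers)[0]
        raise ValueError(f"cycle detected in flow directions involving cell ({r}, {c})")
    return acc


def find_pour_point(
    accumulation: np.ndarray,
    lake_mask: np.ndarray,
    buffer_px: int = 0,
) -> tuple[int, int]:
    """Cell of highest flow accumulation within the (optionally buffered) lake.

    ``buffer_px=1`` dilates the lake by one ring of 8-neighbours, the
    workaround for flat outflow areas. Ties break to the first cell in
    row-major order.
    """
    mask = np.asarray(lake_mask, dtype=bool)
    if not mask.any():
        raise ValueError("lake mask is empty")
    if buffer_px > 0:
        mask = binary_dilation(mask, structure=np.ones((3, 3), bool), iterations=buffer_px)
    search = np.where(mask & np.isfinite(accumulation), accumulation, -np.inf)
    flat_idx = int(np.argmax(search))  # first max in row-major order
    r, c = divmod(flat_idx, accumulation.shape[1])
    if not np.isfinite(search[r, c]):
        raise ValueError("lake mask covers no valid accumulation cells")
    return r, c


def delineate_watershed(direction: np.ndarray, pour_cell: tuple[int, int]) -> np.ndarray:
    """Boolean mask of all cells whose D8 path reaches ``pour_cell``."""
    nrows, ncols = direction.shape
    pr, pc = pour_cell
    if not (0 <= pr < nrows and 0 <= pc < ncols) or direction[pr, pc] == UNDEFINED_CODE:
        raise ValueError(f"pour cell ({pr}, {pc}) is not a valid grid cell")
    upstream: dict[tuple[int, int], list[tuple[int, int]]] = {}
    for r in range(nrows):
        for c in range(ncols):
            if direction[r, c] == UNDEFINED_CODE:
                continue
            ds = downstream_cell(direction, r, c)
            if ds is not None:
                upstream.setdefault(ds, []).append((r, c))
    mask = np.zeros((nrows, ncols), dtype=bool)
    queue = deque([(pr, pc)])
    mask[pr, pc] = True
    while queue:
        cell = queue.popleft()
        for up in upstream.get(cell, ()):
            if not mask[up]:
                mask[up] = True
                queue.append(up)
    return mask


def summarize_landcover(
    landcover: Raster,
    mask: np.ndarray,
    class_map: dict[int, str],
) -> tuple[float, float]:
    """Forest and urban proportions of valid masked cells.

    ``class_map`` sends raster codes to ``{"forest", "urban", "other"}``;
    nodata cells are excluded from the denominator.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("catchment mask is empty")
    cells = landcover.values[mask & landcover.mask_valid()]
    if cells.size == 0:
        raise ValueError("no valid land cover cells inside the mask")
    classes = np.array([class_map.get(int(code), "other") for code in cells])
    forest_prop = float(np.mean(classes == "forest"))
    urban_prop = float(np.mean(classes == "urban"))
    return forest_prop, urban_prop


def sum_wwtw_load(
    wwtw_points: list[tuple[float, float, float]],
    mask: np.ndarray,
    raster: Raster,
) -> float:
    """Total treatment-plant load (population equivalents) inside the mask.

    A plant belongs to the half-open cell containing its coordinates;
    plants on a boundary cell of the mask count as inside.
    """
    mask = np.asarray(mask, dtype=bool)
    total = 0.0
    for x, y, load in wwtw_points:
        if load < 0:
            raise ValueError("wastewater loads must be non-negative")
        cell = raster.cell_of_point(x, y)
        if cell is not None and mask[cell]:
            total += load
    return total


def catchment_summary(
    dem: Raster,
    lake_mask: np.ndarray,
    landcover: Raster,
    class_map: dict[int, str],
    wwtw_points: list[tuple[float, float, float]] | None = None,
    buffer_px: int = 0,
) -> tuple[CatchmentSummary, np.ndarray, FlowField]:
    """Full pipeline: fill, route, pour point, watershed, summaries."""
    filled = fill_depressions(dem)
    direction = d8_flow_direction(filled)
    accumulation = flow_accumulation(direction)
    pour = find_pour_point(accumulation, lake_mask, buffer_px=buffer_px)
    watershed = delineate_watershed(direction, pour)
    forest_prop, urban_prop = summarize_landcover(landcover, watershed, class_map)
    load = sum_wwtw_load(wwtw_points or [], watershed, dem)
    summary = CatchmentSummary(
        area_km2=float(watershed.sum()) * dem.cell_area_km2(),
        forest_prop=forest_prop,
        urban_prop=urban_prop,
        wwtw_load_pe=load,
    )
    return summary, watershed, FlowField(direction=direction, accumulation=accumulation)
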