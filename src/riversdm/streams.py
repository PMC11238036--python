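"""Drainage network derivation and reach characterization.

Pipeline: sink-fill a DEM, route flow with single-direction D8, accumulate,
threshold drainage lines at a minimum contributing area, cut the traced lines
into ~100 m reaches, and attach geophysical attributes (drainage area,
gradient, sinuosity, aspect, Strahler order, valley confinement, network
distances) to every reach.

Conventions
-----------
* D8 neighbour precedence for deterministic ties: E, SE, S, SW, W, NW, N, NE.
* Flow accumulation counts the cell itself, so drainage area =
  accumulation x cell_size^2.
* Cells on a flat left by sink filling drain toward the nearest already
  resolved cell of equal elevation (BFS order, fixed precedence).
"""

from __future__ import annotations

import heapq
import json
import math
from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import ElevationGrid, RasterGrid

__all__ = [
    "FlowGrid",
    "Reach",
    "StreamNetwork",
    "fill_sinks",
    "flow_direction",
    "flow_accumulation",
    "extract_streams",
    "segment_reaches",
    "strahler_order",
    "reach_geometry_attributes",
    "valley_confinement",
    "network_distances",
    "delineate_catchment",
    "characterize_network",
    "find_pits",
    "OUTLET",
    "NODATA_DIR",
    "D8_OFFSETS",
]

# Neighbour offsets (drow, dcol) in fixed precedence order.
D8_OFFSETS: list[tuple[int, int]] = [
    (0, 1),    # E
    (1, 1),    # SE
    (1, 0),    # S
    (1, -1),   # SW
    (0, -1),   # W
    (-1, -1),  # NW
    (-1, 0),   # N
    (-1, 1),   # NE
]
_SQRT2 = math.sqrt(2.0)
D8_DISTANCE = [1.0, _SQRT2, 1.0, _SQRT2, 1.0, _SQRT2, 1.0, _SQRT2]

OUTLET = -1      # drains off the grid (or into nodata)
NODATA_DIR = -9  # no data


@dataclass
class FlowGrid:
    """D8 flow directions and (optionally) flow accumulation."""

    direction: np.ndarray           # int codes: 0..7 index into D8_OFFSETS, OUTLET, NODATA_DIR
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    accumulation: np.ndarray | None = None  # cells draining through, incl. self

    @property
    def shape(self) -> tuple[int, int]:
        return self.direction.shape

    def downstream_cell(self, row: int, col: int) -> tuple[int, int] | None:
        """Cell receiving flow from (row, col), or None at outlets."""
        d = self.direction[row, col]
        if d < 0:
            return None
        dr, dc = D8_OFFSETS[d]
        r, c = row + dr, col + dc
        if not (0 <= r < self.shape[0] and 0 <= c < self.shape[1]):
            return None
        return r, c


def _valid_mask(dem: ElevationGrid) -> np.ndarray:
    return dem.mask_valid()


def find_pits(dem: ElevationGrid) -> list[tuple[int, int]]:
    """Brute-force 8-neighbour scan for interior pits.

    A pit is a valid cell, not on the boundary of the valid region, with no
    neighbour at strictly lower or equal elevation that itself escapes -- here
    simplified to: no 8-neighbour with elevation <= its own minus nothing,
    i.e. every neighbour is strictly higher.  Used as an independent check of
    :func:`fill_sinks`; flats that drain are not pits.
    """
    z = dem.values
    valid = _valid_mask(dem)
    nr, nc = z.shape
    pits = []
    for r in range(nr):
        for c in range(nc):
            if not valid[r, c]:
                continue
            on_edge = False
            lower_or_equal = False
            for dr, dc in D8_OFFSETS:
                rr, cc = r + dr, c + dc
                if not (0 <= rr < nr and 0 <= cc < nc) or not valid[rr, cc]:
                    on_edge = True
                    break
                if z[rr, cc] <= z[r, c]:
                    lower_or_equal = True
            if not on_edge and not lower_or_equal:
                pits.append((r, c))
    return pits


def fill_sinks(dem: ElevationGrid) -> ElevationGrid:
    """Priority-flood sink filling.

    Raises every cell trapped in a depression to its pour-point elevation so
    that each interior cell has a monotone non-increasing path to the
    boundary.  Output >= input everywhere; cells already draining are
    untouched.
    """
    z = dem.values
    valid = _valid_mask(dem)
    if not valid.any():
        raise ValueError("all-nodata grid cannot be filled")
    nr, nc = z.shape
    filled = np.where(valid, z, np.nan)
    closed = ~valid.copy()
    heap: list[tuple[float, int, int, int]] = []
    counter = 0
    # Seed: valid cells on the grid edge or adjacent to nodata.
    for r in range(nr):
        for c in range(nc):
            if not valid[r, c]:
                continue
            edge = r in (0, nr - 1) or c in (0, nc - 1)
            if not edge:
                for dr, dc in D8_OFFSETS:
                    rr, cc = r + dr, c + dc
                    if not valid[rr, cc]:
                        edge = True
                        break
            if edge:
                heapq.heappush(heap, (filled[r, c], counter, r, c))
                counter += 1
                closed[r, c] = True
    while heap:
        zc, _, r, c = heapq.heappop(heap)
        for dr, dc in D8_OFFSETS:
            rr, cc = r + dr, c + dc
            if 0 <= rr < nr and 0 <= cc < nc and not closed[rr, cc]:
                closed[rr, cc] = True
                fz = max(filled[rr, cc], zc)
                filled[rr, cc] = fz
                heapq.heappush(heap, (fz, counter, rr, cc))
                counter += 1
    out = dem.like(np.where(valid, filled, dem.values))
    return out


def flow_direction(filled_dem: ElevationGrid) -> FlowGrid:
    """D8 steepest-descent flow directions on a sink-filled DEM.

    Each cell points to the neighbour with the greatest drop/distance
    (diagonal distance sqrt(2) x cell).  Boundary cells with no lower
    neighbour are outlets.  Cells on interior flats are resolved by BFS
    toward the nearest resolved cell of equal elevation.
    """
    z = filled_dem.values
    valid = _valid_mask(filled_dem)
    nr, nc = z.shape
    direction = np.full((nr, nc), NODATA_DIR, dtype=int)
    cs = filled_dem.cell_size

    resolved = deque()
    unresolved_flats = []
    for r in range(nr):
        for c in range(nc):
            if not valid[r, c]:
                continue
            best_slope = 0.0
            best_dir = None
            boundary = False
            for k, (dr, dc) in enumerate(D8_OFFSETS):
                rr, cc = r + dr, c + dc
                if not (0 <= rr < nr and 0 <= cc < nc) or not valid[rr, cc]:
                    boundary = True
                    continue
                slope = (z[r, c] - z[rr, cc]) / (D8_DISTANCE[k] * cs)
                if slope > best_slope:  # strict: ties keep earlier precedence
                    best_slope = slope
                    best_dir = k
            if best_dir is not None:
                direction[r, c] = best_dir
                resolved.append((r, c))
            elif boundary:
                direction[r, c] = OUTLET
                resolved.append((r, c))
            else:
                unresolved_flats.append((r, c))

    # Resolve flats: BFS from resolved cells across equal-elevation neighbours.
    pending = {rc for rc in unresolved_flats}
    while resolved:
        r, c = resolved.popleft()
        for k, (dr, dc) in enumerate(D8_OFFSETS):
            rr, cc = r + dr, c + dc
            if (rr, cc) in pending and z[rr, cc] == z[r, c]:
                # direction from (rr,cc) back to (r,c) is the opposite offset
                direction[rr, cc] = (k + 4) % 8
                pending.discard((rr, cc))
                resolved.append((rr, cc))
    if pending:
        raise ValueError(
            f"{len(pending)} cells on unresolvable flats; DEM not sink-filled?"
        )
    return FlowGrid(direction=direction, cell_size=filled_dem.cell_size,
                    origin=filled_dem.origin)


def flow_accumulation(flow: FlowGrid) -> FlowGrid:
    """Count cells draining through each cell (including itself).

    Topological (Kahn) propagation over the direction graph; raises if the
    directions contain a cycle.
    """
    nr, nc = flow.shape
    direction = flow.direction
    acc = np.where(direction != NODATA_DIR, 1, 0).astype(np.int64)
    indeg = np.zeros((nr, nc), dtype=int)
    for r in range(nr):
        for c in range(nc):
            if direction[r, c] >= 0:
                ds = flow.downstream_cell(r, c)
                if ds is not None:
                    indeg[ds] += 1
    queue = deque(
        (r, c)
        for r in range(nr)
        for c in range(nc)
        if direction[r, c] != NODATA_DIR and indeg[r, c] == 0
    )
    processed = 0
    total = int((direction != NODATA_DIR).sum())
    while queue:
        r, c = queue.popleft()
        processed += 1
        ds = flow.downstream_cell(r, c)
        if ds is not None and direction[ds] != NODATA_DIR:
            acc[ds] += acc[r, c]
            indeg[ds] -= 1
            if indeg[ds] == 0:
                queue.append(ds)
    if processed != total:
        raise ValueError("cycle detected in flow directions")
    return FlowGrid(direction=direction, cell_size=flow.cell_size,
                    origin=flow.origin, accumulation=acc)


def extract_streams(flow: FlowGrid, min_area_km2: float = 0.1) -> np.ndarray:
    """Mask of stream cells: drainage area >= min_area_km2."""
    if min_area_km2 <= 0:
        raise ValueError("min_area_km2 must be positive")
    if flow.accumulation is None:
        raise ValueError("accumulation not computed; run flow_accumulation")
    area_km2 = flow.accumulation * (flow.cell_size ** 2) / 1e6
    return area_km2 >= min_area_km2


@dataclass
class Reach:
    """A ~100 m stream segment with geophysical attributes."""

    id: int
    vertices: np.ndarray                    # (k, 2) xy polyline, metres
    cells: list[tuple[int, int]]            # stream cells assigned to this reach
    length: float                           # metres
    downstream_reach: int | None = None
    drainage_area: float = float("nan")     # km^2
    gradient: float = float("nan")          # %
    sinuosity: float = float("nan")
    aspect: float = float("nan")            # degrees clockwise from north
    strahler: int = 0
    valley_confinement: float = float("nan")
    dist_downstream: float = float("nan")   # km
    dist_upstream: float = float("nan")     # km
    elevation: float = float("nan")         # metres
    basin: int = -1

    @property
    def midpoint(self) -> tuple[float, float]:
        return tuple(_point_at_chainage(self.vertices, self.length / 2.0))

    @property
    def midpoint_cell(self) -> tuple[int, int]:
        # stored during segmentation
        return self._mid_cell

    @property
    def anchor_cells(self) -> list[tuple[int, int]]:
        """Owned cells, or the midpoint cell for reaches that own none."""
        return self.cells if self.cells else [self._mid_cell]

    _mid_cell: tuple[int, int] = field(default=(0, 0), repr=False)


@dataclass
class StreamNetwork:
    """Reaches plus downstream topology (a forest rooted at outlets)."""

    reaches: dict[int, Reach]
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __len__(self) -> int:
        return len(self.reaches)

    def upstream_map(self) -> dict[int, list[int]]:
        up: dict[int, list[int]] = {rid: [] for rid in self.reaches}
        for rid, reach in self.reaches.items():
            if reach.downstream_reach is not None:
                up[reach.downstream_reach].append(rid)
        for lst in up.values():
            lst.sort()
        return up

    def outlets(self) -> list[int]:
        return sorted(
            rid for rid, r in self.reaches.items() if r.downstream_reach is None
        )

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for rid in sorted(self.reaches):
            r = self.reaches[rid]
            rows.append({
                "reach_id": rid,
                "length_m": r.length,
                "drainage_area_km2": r.drainage_area,
                "gradient_pct": r.gradient,
                "sinuosity": r.sinuosity,
                "aspect_deg": r.aspect,
                "strahler": r.strahler,
                "valley_confinement": r.valley_confinement,
                "dist_downstream_km": r.dist_downstream,
                "dist_upstream_km": r.dist_upstream,
                "elevation_m": r.elevation,
                "basin": r.basin,
                "downstream_reach": (
                    r.downstream_reach if r.downstream_reach is not None else -1
                ),
            })
        return pd.DataFrame(rows)

    def to_geojson(self) -> dict:
        features = []
        for rid in sorted(self.reaches):
            r = self.reaches[rid]
            features.append({
                "type": "Feature",
                "geometry": {
                    "type": "LineString",
                    "coordinates": [[float(x), float(y)] for x, y in r.vertices],
                },
                "properties": {
                    "reach_id": rid,
                    "length_m": r.length,
                    "strahler": r.strahler,
                    "downstream_reach": r.downstream_reach,
                },
            })
        return {"type": "FeatureCollection", "features": features}

    def write_geojson(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_geojson(), fh)


def _point_at_chainage(vertices: np.ndarray, s: float) -> np.ndarray:
    """Interpolate a point at distance s along a polyline."""
    if len(vertices) == 1:
        return vertices[0].astype(float)
    seg = np.diff(vertices, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    s = min(max(s, 0.0), cum[-1])
    i = int(np.searchsorted(cum, s, side="right")) - 1
    i = min(i, len(seg_len) - 1)
    if seg_len[i] == 0:
        return vertices[i].astype(float)
    t = (s - cum[i]) / seg_len[i]
    return vertices[i] + t * seg[i]


def _trace_links(
    mask: np.ndarray, flow: FlowGrid
) -> tuple[list[list[tuple[int, int]]], dict[int, int | None]]:
    """Split the stream cell graph into links between junctions.

    Returns (links, downstream_link) where each link is an ordered list of
    stream cells and downstream_link maps link index -> index of the link its
    last cell drains into (None at outlets).  A junction cell heads the link
    downstream of it.
    """
    nr, nc = mask.shape
    inflows = np.zeros((nr, nc), dtype=int)
    for r in range(nr):
        for c in range(nc):
            if mask[r, c]:
                ds = flow.downstream_cell(r, c)
                if ds is not None and mask[ds]:
                    inflows[ds] += 1
    starts = [
        (r, c)
        for r in range(nr)
        for c in range(nc)
        if mask[r, c] and inflows[r, c] != 1
    ]
    links: list[list[tuple[int, int]]] = []
    head_of: dict[tuple[int, int], int] = {}
    for start in starts:
        link = [start]
        cur = start
        while True:
            ds = flow.downstream_cell(*cur)
            if ds is None or not mask[ds] or inflows[ds] >= 2:
                break
            link.append(ds)
            cur = ds
        head_of[start] = len(links)
        links.append(link)
    downstream_link: dict[int, int | None] = {}
    for i, link in enumerate(links):
        ds = flow.downstream_cell(*link[-1])
        if ds is not None and mask[ds]:
            downstream_link[i] = head_of[ds]
        else:
            downstream_link[i] = None
    return links, downstream_link


def segment_reaches(
    mask: np.ndarray,
    flow: FlowGrid,
    target_length: float = 100.0,
) -> StreamNetwork:
    """Cut downstream-traced drainage lines into ~target_length reaches.

    Each link (stretch between junctions) is cut at exact chainage multiples
    of target_length; a trailing remainder <= target_length/2 is merged into
    the previous reach, a longer one becomes its own (shorter) reach.  Every
    stream cell is assigned to exactly one reach.
    """
    if not mask.any():
        raise ValueError("empty stream mask")
    grid = RasterGrid(np.zeros(mask.shape), flow.cell_size, flow.origin)
    links, downstream_link = _trace_links(mask, flow)

    reaches: dict[int, Reach] = {}
    next_id = 0
    link_first_reach: dict[int, int] = {}
    link_last_reach: dict[int, int] = {}

    for li, link in enumerate(links):
        cells = list(link)
        ds_cell = flow.downstream_cell(*link[-1])
        verts = [grid.cell_center(r, c) for r, c in cells]
        closing = ds_cell is not None and mask[ds_cell]
        if closing:
            verts.append(grid.cell_center(*ds_cell))
        vertices = np.asarray(verts, dtype=float)
        seg = np.diff(vertices, axis=0)
        seg_len = np.hypot(seg[:, 0], seg[:, 1]) if len(vertices) > 1 else np.array([])
        cum = np.concatenate([[0.0], np.cumsum(seg_len)])
        total = float(cum[-1])

        if total <= 0.0:
            cuts = [0.0, 0.0]
        else:
            n_full = int(total // target_length)
            remainder = total - n_full * target_length
            bounds = [i * target_length for i in range(n_full + 1)]
            if remainder > target_length / 2.0 + 1e-9:
                bounds.append(total)
            else:
                if n_full == 0:
                    bounds = [0.0, total]
                else:
                    bounds[-1] = total
            cuts = bounds
            if len(cuts) < 2:
                cuts = [0.0, total]

        link_reach_ids = []
        for a, b in zip(cuts[:-1], cuts[1:]):
            rid = next_id
            next_id += 1
            # polyline piece between chainages a and b
            if len(vertices) == 1 or total <= 0.0:
                piece = np.vstack([vertices[0], vertices[0]])
            else:
                vmask = (cum > a + 1e-9) & (cum < b - 1e-9)
                pts = [_point_at_chainage(vertices, a)]
                pts.extend(vertices[1:-1][vmask[1:-1]] if len(vertices) > 2 else [])
                pts.append(_point_at_chainage(vertices, b))
                piece = np.asarray(pts, dtype=float)
            # cells whose vertex chainage falls inside [a, b); closing vertex
            # belongs to the downstream link
            last = b >= total - 1e-9
            cell_idx = [
                k for k in range(len(cells))
                if (a - 1e-9) <= cum[k] and (cum[k] < b - 1e-9 or last)
            ]
            # exact partition: a reach whose interval is narrower than the
            # vertex spacing may own no cell; it then anchors on _mid_cell
            assigned = [cells[k] for k in cell_idx]
            reach = Reach(
                id=rid,
                vertices=piece,
                cells=assigned,
                length=float(b - a) if b > a else float(flow.cell_size),
            )
            mid_pt = _point_at_chainage(vertices, (a + b) / 2.0)
            k = int(np.argmin(np.hypot(
                np.asarray([grid.cell_center(r, c) for r, c in cells])[:, 0] - mid_pt[0],
                np.asarray([grid.cell_center(r, c) for r, c in cells])[:, 1] - mid_pt[1],
            )))
            reach._mid_cell = cells[k]
            reaches[rid] = reach
            link_reach_ids.append(rid)
        # chain within link
        for u, d in zip(link_reach_ids[:-1], link_reach_ids[1:]):
            reaches[u].downstream_reach = d
        link_first_reach[li] = link_reach_ids[0]
        link_last_reach[li] = link_reach_ids[-1]

    # connect links
    for li, dli in downstream_link.items():
        if dli is not None:
            reaches[link_last_reach[li]].downstream_reach = link_first_reach[dli]

    net = StreamNetwork(reaches=reaches, cell_size=flow.cell_size,
                        origin=flow.origin)
    _assign_basins(net)
    return net


def _assign_basins(net: StreamNetwork) -> None:
    """Basin id = id of the outlet reach each reach ultimately drains to."""
    cache: dict[int, int] = {}

    def root(rid: int) -> int:
        path = []
        while rid not in cache and net.reaches[rid].downstream_reach is not None:
            path.append(rid)
            rid = net.reaches[rid].downstream_reach
        res = cache.get(rid, rid)
        for p in path:
            cache[p] = res
        return res

    for rid, reach in net.reaches.items():
        reach.basin = root(rid)


def strahler_order(net: StreamNetwork) -> dict[int, int]:
    """Strahler order per reach: headwaters 1, equal-order junctions +1."""
    up = net.upstream_map()
    order: dict[int, int] = {}
    # process upstream-first (topological over downstream links)
    indeg = {rid: len(up[rid]) for rid in net.reaches}
    queue = deque(rid for rid, d in indeg.items() if d == 0)
    while queue:
        rid = queue.popleft()
        ups = [order[u] for u in up[rid]]
        if not ups:
            order[rid] = 1
        else:
            m = max(ups)
            order[rid] = m + 1 if ups.count(m) >= 2 else m
        ds = net.reaches[rid].downstream_reach
        if ds is not None:
            indeg[ds] -= 1
            if indeg[ds] == 0:
                queue.append(ds)
    for rid, o in order.items():
        net.reaches[rid].strahler = o
    return order


def _horn_aspect(dem: ElevationGrid, row: int, col: int) -> float:
    """Downslope direction by Horn's method, degrees clockwise from north."""
    z = np.pad(dem.values, 1, mode="edge")
    r, c = row + 1, col + 1
    a, b_, cc = z[r - 1, c - 1], z[r - 1, c], z[r - 1, c + 1]
    d, f = z[r, c - 1], z[r, c + 1]
    g, h, i = z[r + 1, c - 1], z[r + 1, c], z[r + 1, c + 1]
    cs = dem.cell_size
    dzdx = ((cc + 2 * f + i) - (a + 2 * d + g)) / (8 * cs)   # eastward
    dzdy = ((a + 2 * b_ + cc) - (g + 2 * h + i)) / (8 * cs)  # northward
    if dzdx == 0 and dzdy == 0:
        return float("nan")
    return float(math.degrees(math.atan2(-dzdx, -dzdy)) % 360.0)


def reach_geometry_attributes(reach: Reach, dem: ElevationGrid) -> Reach:
    """Gradient (%), sinuosity, aspect (deg) and midpoint elevation (m)."""
    v = reach.vertices
    if reach.length <= 0 or len(v) < 2:
        raise ValueError("degenerate zero-length reach")
    seg = np.diff(v, axis=0)
    path_len = float(np.hypot(seg[:, 0], seg[:, 1]).sum())
    straight = float(np.hypot(*(v[-1] - v[0])))
    reach.sinuosity = path_len / straight if straight > 0 else 1.0
    if path_len <= 0:  # degenerate single-cell link
        path_len = reach.length

    def elev_at(pt) -> float:
        try:
            r, c = dem.index_of(pt[0], pt[1])
        except IndexError:
            r = min(max(dem.n_rows - 1 - int(pt[1] // dem.cell_size), 0), dem.n_rows - 1)
            c = min(max(int(pt[0] // dem.cell_size), 0), dem.n_cols - 1)
        return float(dem.values[r, c])

    z_up, z_down = elev_at(v[0]), elev_at(v[-1])
    reach.gradient = max(0.0, 100.0 * (z_up - z_down) / path_len)
    mr, mc = reach.midpoint_cell
    reach.aspect = _horn_aspect(dem, mr, mc)
    reach.elevation = float(dem.values[mr, mc])
    return reach


def valley_confinement(
    reach: Reach,
    dem: ElevationGrid,
    search_radius: float = 300.0,
    relief_threshold: float = 10.0,
) -> float:
    """Confinement index in [0, 1] around the reach midpoint.

    1 - fraction of cells within search_radius whose elevation is within
    relief_threshold of the reach elevation: 0 = broad open valley, 1 = fully
    confined.  Windows overlapping the grid edge are clipped.
    """
    if search_radius < dem.cell_size:
        raise ValueError("search_radius must be at least one cell")
    mr, mc = reach.midpoint_cell
    z0 = float(dem.values[mr, mc])
    w = int(math.ceil(search_radius / dem.cell_size))
    r0, r1 = max(0, mr - w), min(dem.n_rows, mr + w + 1)
    c0, c1 = max(0, mc - w), min(dem.n_cols, mc + w + 1)
    rows, cols = np.mgrid[r0:r1, c0:c1]
    dist = np.hypot(rows - mr, cols - mc) * dem.cell_size
    window = dist <= search_radius
    zw = dem.values[r0:r1, c0:c1][window]
    zw = zw[np.isfinite(zw)]
    if zw.size == 0:
        raise ValueError("window contains no valid cells")
    frac_low = float((zw <= z0 + relief_threshold).mean())
    idx = 1.0 - frac_low
    reach.valley_confinement = idx
    return idx


def network_distances(net: StreamNetwork) -> None:
    """Fill dist_downstream (to outlet) and dist_upstream (to headwaters), km.

    Both include the reach's own length; dist_upstream takes the longest
    upstream path.
    """
    up = net.upstream_map()
    order: list[int] = []
    indeg = {rid: len(up[rid]) for rid in net.reaches}
    queue = deque(rid for rid, d in indeg.items() if d == 0)
    while queue:
        rid = queue.popleft()
        order.append(rid)
        ds = net.reaches[rid].downstream_reach
        if ds is not None:
            indeg[ds] -= 1
            if indeg[ds] == 0:
                queue.append(ds)
    # upstream-first for dist_upstream
    for rid in order:
        r = net.reaches[rid]
        ups = [net.reaches[u].dist_upstream for u in up[rid]]
        r.dist_upstream = r.length / 1000.0 + (max(ups) if ups else 0.0)
    # downstream-first for dist_downstream
    for rid in reversed(order):
        r = net.reaches[rid]
        ds = r.downstream_reach
        tail = net.reaches[ds].dist_downstream if ds is not None else 0.0
        r.dist_downstream = r.length / 1000.0 + tail


def flow_accumulate_weights(flow: FlowGrid, weights: np.ndarray) -> np.ndarray:
    """Sum an arbitrary per-cell weight field over each cell's upstream set.

    Same topological propagation as :func:`flow_accumulation` but with
    user-supplied initial values (the cell's own weight is included), so the
    catchment mean of a field at a cell is
    ``accumulate(field)[cell] / accumulation[cell]``.
    """
    nr, nc = flow.shape
    direction = flow.direction
    acc = np.where(direction != NODATA_DIR, weights, 0.0).astype(float)
    indeg = np.zeros((nr, nc), dtype=int)
    for r in range(nr):
        for c in range(nc):
            if direction[r, c] >= 0:
                ds = flow.downstream_cell(r, c)
                if ds is not None:
                    indeg[ds] += 1
    queue = deque(
        (r, c)
        for r in range(nr)
        for c in range(nc)
        if direction[r, c] != NODATA_DIR and indeg[r, c] == 0
    )
    while queue:
        r, c = queue.popleft()
        ds = flow.downstream_cell(r, c)
        if ds is not None and direction[ds] != NODATA_DIR:
            acc[ds] += acc[r, c]
            indeg[ds] -= 1
            if indeg[ds] == 0:
                queue.append(ds)
    return acc


def delineate_catchment(reach: Reach, flow: FlowGrid) -> set[tuple[int, int]]:
    """All cells whose flow path passes through any cell of the reach."""
    nr, nc = flow.shape
    inflow_lists: dict[tuple[int, int], list[tuple[int, int]]] = {}
    for r in range(nr):
        for c in range(nc):
            if flow.direction[r, c] == NODATA_DIR:
                continue
            ds = flow.downstream_cell(r, c)
            if ds is not None:
                inflow_lists.setdefault(ds, []).append((r, c))
    catchment: set[tuple[int, int]] = set(reach.anchor_cells)
    queue = deque(reach.anchor_cells)
    while queue:
        cell = queue.popleft()
        for upc in inflow_lists.get(cell, ()):
            if upc not in catchment:
                catchment.add(upc)
                queue.append(upc)
    return catchment


def characterize_network(
    net: StreamNetwork,
    filled_dem: ElevationGrid,
    flow: FlowGrid,
    search_radius: float = 300.0,
    relief_threshold: float = 10.0,
) -> StreamNetwork:
    """Attach all geophysical attributes to every reach in place."""
    if flow.accumulation is None:
        raise ValueError("flow accumulation required")
    cell_km2 = (flow.cell_size ** 2) / 1e6
    for reach in net.reaches.values():
        reach_geometry_attributes(reach, filled_dem)
        valley_confinement(reach, filled_dem, search_radius, relief_threshold)
        # most-downstream assigned cell carries the reach's drainage area
        accs = [flow.accumulation[r, c] for r, c in reach.anchor_cells]
        reach.drainage_area = float(max(accs) * cell_km2)
    strahler_order(net)
    network_distances(net)
    return net
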