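"""Breeding-territory geometry from nest-box coordinates.

Territories are approximated by Thiessen (Voronoi) polygons around the
occupied breeding boxes of one season, clipped to a study-area polygon.
Every nest-box — occupied or not — is assigned to the territory of its
nearest occupied box.  Two territories are neighbors ("1st order") when
their polygons share a border of positive length; higher neighborhood
orders are shortest-path distances in that adjacency graph.

All coordinates are planar meters; geographic input must be projected
upstream (the study plots this targets are well under a kilometer
across, so a local projection is exact for practical purposes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from shapely.geometry import MultiPoint, Point, Polygon
from shapely.ops import voronoi_diagram
from shapely.strtree import STRtree

logger = logging.getLogger(__name__)

#: Sentinel returned by :func:`neighbor_order` for territories in different
#: connected components of the adjacency graph.  Deliberately not a number,
#: so it can never silently enter an arithmetic pipeline.
UNREACHABLE = object()

#: Minimum shared-border length (meters) for two clipped Voronoi cells to
#: count as adjacent.  Point contacts (zero-length intersections, as in a
#: perfectly regular grid's diagonal neighbors) are not adjacency.
ADJACENCY_TOL = 1e-6


@dataclass(frozen=True)
class NestBox:
    """A nest-box at planar coordinates (meters)."""

    box_id: str
    x: float
    y: float


@dataclass(frozen=True)
class StudyArea:
    """Simple polygon bounding the study plot; clips unbounded Voronoi cells."""

    boundary: Polygon

    def __post_init__(self) -> None:
        if not self.boundary.is_valid or self.boundary.is_empty:
            raise ValueError("study-area boundary must be a valid, non-empty polygon")

    @property
    def area(self) -> float:
        return self.boundary.area

    def contains_point(self, x: float, y: float) -> bool:
        return self.boundary.covers(Point(x, y))

    @classmethod
    def from_boxes(cls, boxes: pd.DataFrame, buffer: float | None = None) -> "StudyArea":
        """Convex hull of all boxes, buffered outward.

        The default buffer is half the mean nearest-neighbor spacing, which
        keeps edge territories finite without distorting adjacency among
        interior cells.
        """
        xy = boxes[["x", "y"]].to_numpy(float)
        if buffer is None:
            if len(xy) >= 2:
                d = cdist(xy, xy)
                np.fill_diagonal(d, np.inf)
                buffer = 0.5 * float(d.min(axis=1).mean())
            else:
                buffer = 50.0
        hull = MultiPoint([tuple(p) for p in xy]).convex_hull.buffer(buffer)
        return cls(boundary=hull)


@dataclass
class TerritoryMap:
    """Per-season tessellation of the study area into breeding territories.

    ``territories`` maps territory_id -> (breeding box_id, polygon); the
    territory_id of a territory is the id of its breeding box.
    """

    year: int
    area: StudyArea
    territories: dict[str, tuple[str, Polygon]]
    generators: pd.DataFrame  # territory_id, box_id, x, y
    box_assignment: dict[str, str]
    adjacency: nx.Graph = field(repr=False)

    @property
    def territory_ids(self) -> list[str]:
        return list(self.territories)

    def polygon(self, territory_id: str) -> Polygon:
        return self.territories[territory_id][1]

    def breeding_box(self, territory_id: str) -> str:
        return self.territories[territory_id][0]

    def boxes_in(self, territory_id: str) -> list[str]:
        return [b for b, t in self.box_assignment.items() if t == territory_id]

    def orders_from(self, territory_id: str) -> dict[str, int]:
        """Neighborhood order from one territory to every reachable one."""
        return dict(nx.single_source_shortest_path_length(self.adjacency, territory_id))

    def adjacency_edges(self) -> pd.DataFrame:
        rows = [
            {"territory_a": a, "territory_b": b}
            for a, b in sorted(tuple(sorted(e)) for e in self.adjacency.edges)
        ]
        return pd.DataFrame(rows, columns=["territory_a", "territory_b"])

    def to_geojson(self) -> dict:
        feats = []
        for tid, (bid, poly) in self.territories.items():
            feats.append(
                {
                    "type": "Feature",
                    "properties": {"territory_id": tid, "box_id": bid, "year": self.year},
                    "geometry": poly.__geo_interface__,
                }
            )
        return {"type": "FeatureCollection", "features": feats}


def _as_box_frame(boxes) -> pd.DataFrame:
    if isinstance(boxes, pd.DataFrame):
        df = boxes.copy()
        if "x_m" in df.columns:
            df = df.rename(columns={"x_m": "x", "y_m": "y"})
    else:
        df = pd.DataFrame(
            [{"box_id": b.box_id, "x": b.x, "y": b.y} for b in boxes]
        )
    df["box_id"] = df["box_id"].astype(str)
    xy = df[["x", "y"]].to_numpy(float)
    if not np.isfinite(xy).all():
        raise ValueError("nest-box coordinates must be finite")
    if df["box_id"].duplicated().any():
        dupes = df.loc[df["box_id"].duplicated(), "box_id"].tolist()
        raise ValueError(f"duplicate box_id(s): {dupes}")
    if pd.DataFrame(xy).duplicated().any():
        raise ValueError("two nest-boxes at identical coordinates")
    return df


def build_territories(
    boxes,
    attempts: pd.DataFrame,
    area: StudyArea | None = None,
    year: int | None = None,
) -> TerritoryMap:
    """Tessellate one season's occupied breeding boxes into territories.

    Parameters
    ----------
    boxes
        All nest-boxes (DataFrame with box_id, x, y or iterable of NestBox).
    attempts
        Breeding attempts of one season; each attempt's ``box_id`` becomes a
        territory generator.  Two attempts on the same box is an error.
    area
        Study-area polygon; defaults to the buffered convex hull of the boxes.
    """
    box_df = _as_box_frame(boxes)
    if area is None:
        area = StudyArea.from_boxes(box_df)
    if year is None:
        year = int(attempts["year"].iloc[0]) if "year" in attempts.columns and len(attempts) else 0

    if len(attempts) == 0:
        raise ValueError("no occupied breeding boxes: cannot build territories")
    occ_ids = [str(b) for b in attempts["box_id"]]
    if len(set(occ_ids)) != len(occ_ids):
        dupes = sorted({b for b in occ_ids if occ_ids.count(b) > 1})
        raise ValueError(f"two breeding attempts share box(es) {dupes} in the same season")
    missing = set(occ_ids) - set(box_df["box_id"])
    if missing:
        raise ValueError(f"breeding box(es) not in box table: {sorted(missing)}")

    gen = (
        box_df.set_index("box_id")
        .loc[sorted(set(occ_ids))]
        .reset_index()
        .rename(columns={"box_id": "territory_id"})
    )
    gen["box_id"] = gen["territory_id"]
    gen_xy = gen[["x", "y"]].to_numpy(float)

    for _, row in box_df.iterrows():
        if not area.contains_point(row["x"], row["y"]):
            raise ValueError(f"box {row['box_id']} lies outside the study area")

    cells = _voronoi_cells(gen_xy, area)
    territories = {
        tid: (tid, cell) for tid, cell in zip(gen["territory_id"], cells)
    }

    adjacency = _adjacency_graph(list(gen["territory_id"]), cells)

    # every box -> territory of nearest occupied box (ties -> smallest id)
    box_assignment: dict[str, str] = {}
    all_xy = box_df[["x", "y"]].to_numpy(float)
    dists = cdist(all_xy, gen_xy)
    tids = list(gen["territory_id"])
    for i, bid in enumerate(box_df["box_id"]):
        box_assignment[bid] = _nearest_tid(dists[i], tids, bid)

    return TerritoryMap(
        year=year,
        area=area,
        territories=territories,
        generators=gen[["territory_id", "box_id", "x", "y"]],
        box_assignment=box_assignment,
        adjacency=adjacency,
    )


def _nearest_tid(drow: np.ndarray, tids: list[str], box_id: str) -> str:
    dmin = drow.min()
    winners = sorted(tids[j] for j in np.flatnonzero(np.isclose(drow, dmin, rtol=0, atol=1e-9)))
    if len(winners) > 1:
        logger.info(
            "box %s equidistant to territories %s; assigned to %s", box_id, winners, winners[0]
        )
    return winners[0]


def _voronoi_cells(gen_xy: np.ndarray, area: StudyArea) -> list[Polygon]:
    """Voronoi cells of the generators clipped to the study area, in generator order."""
    if len(gen_xy) == 1:
        return [area.boundary]
    minx, miny, maxx, maxy = area.boundary.bounds
    pad = max(maxx - minx, maxy - miny) + 1.0
    envelope = Polygon(
        [
            (minx - pad, miny - pad),
            (maxx + pad, miny - pad),
            (maxx + pad, maxy + pad),
            (minx - pad, maxy + pad),
        ]
    )
    raw = voronoi_diagram(MultiPoint([tuple(p) for p in gen_xy]), envelope=envelope)
    cells_raw = list(raw.geoms)
    tree = STRtree(cells_raw)
    cells: list[Polygon] = []
    for p in gen_xy:
        pt = Point(*p)
        hit = None
        for idx in tree.query(pt):
            if cells_raw[idx].covers(pt):
                hit = cells_raw[idx]
                break
        if hit is None:  # numerical edge case: fall back to nearest cell
            hit = min(cells_raw, key=lambda c: c.distance(pt))
        cells.append(hit.intersection(area.boundary))
    return cells


def _adjacency_graph(tids: list[str], cells: list[Polygon]) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(tids)
    tree = STRtree(cells)
    for i, cell in enumerate(cells):
        for j in tree.query(cell):
            j = int(j)
            if j <= i:
                continue
            inter = cell.intersection(cells[j])
            if inter.length > ADJACENCY_TOL:
                g.add_edge(tids[i], tids[j])
    return g


def neighbor_order(tm: TerritoryMap, a: str, b: str):
    """Shortest-path length between territories in the adjacency graph.

    0 iff ``a == b``; 1 iff adjacent; :data:`UNREACHABLE` (not a number)
    when the two territories lie in different connected components.
    """
    if a not in tm.territories or b not in tm.territories:
        raise KeyError(f"unknown territory id: {a if a not in tm.territories else b}")
    try:
        return nx.shortest_path_length(tm.adjacency, a, b)
    except nx.NetworkXNoPath:
        return UNREACHABLE


def assign_box(tm: TerritoryMap, box: NestBox) -> str:
    """Territory whose breeding box is nearest to ``box`` (ties -> smallest id)."""
    gxy = tm.generators[["x", "y"]].to_numpy(float)
    d = np.hypot(gxy[:, 0] - box.x, gxy[:, 1] - box.y)
    return _nearest_tid(d, list(tm.generators["territory_id"]), box.box_id)


def box_distance(a: NestBox, b: NestBox) -> float:
    """Euclidean distance between two boxes, meters."""
    return float(np.hypot(a.x - b.x, a.y - b.y))


def order_distance_correlation(dyads: pd.DataFrame) -> float:
    """Pearson correlation between neighborhood order and distance over dyads."""
    if len(dyads) < 3:
        raise ValueError("need at least 3 dyads")
    o = dyads["neighbor_order"].to_numpy(float)
    d = dyads["distance"].to_numpy(float)
    if np.ptp(o) == 0 or np.ptp(d) == 0:
        raise ValueError("zero variance in neighbor_order or distance")
    return float(np.corrcoef(o, d)[0, 1])


def mean_unoccupied_per_territory(tm: TerritoryMap) -> float:
    """Average number of non-breeding boxes assigned to each territory."""
    counts = {tid: 0 for tid in tm.territories}
    for bid, tid in tm.box_assignment.items():
        if bid != tm.breeding_box(tid):
            counts[tid] += 1
    return float(np.mean(list(counts.values())))


def mean_neighbor_spacing(boxes, k: int = 4) -> float:
    """Mean distance from each box to its k nearest neighboring boxes."""
    df = _as_box_frame(boxes)
    xy = df[["x", "y"]].to_numpy(float)
    if len(xy) <= k:
        raise ValueError(f"need more than {k} boxes")
    d = cdist(xy, xy)
    np.fill_diagonal(d, np.inf)
    d.sort(axis=1)
    return float(d[:, :k].mean())
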