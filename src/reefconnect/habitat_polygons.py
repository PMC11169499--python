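"""Regionalization of reef habitat hexagons into site polygons.

The habitat map is split by geomorphic zone; within each zone a Delaunay
triangulation of hexagon centroids yields a connected adjacency graph even
when the zone's hexagons form spatially separate patches (the reason
triangulation is preferred over nearest-neighbour adjacency).  Edges carry
the weight

    w_ij = sqrt(v_ij**2 + (d_i - d_j)**2)

where v_ij is the normalized centroid distance between hexagons i and j
and d_i, d_j their depths in metres.  A minimum spanning tree of this
graph is then partitioned into contiguous clusters of at least
``min_size`` hexagons, greedily removing the tree edge whose removal most
reduces within-cluster depth heterogeneity, until the mean cluster area
falls to the target site area.  Each resulting cluster is one site
polygon: a release/settlement unit of the connectivity analysis.

Centroid distances are normalized by the largest Delaunay edge length
within the zone graph; depth differences stay in metres.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay, QhullError
from shapely.geometry import Polygon, mapping, shape
from shapely.ops import unary_union

from .synthetic_environment import HexagonMap, Hexagon

DEFAULT_MIN_SIZE = 200
DEFAULT_TARGET_AREA = 62_500.0


@dataclass
class HexGraph:
    """Weighted undirected adjacency graph over one zone's hexagons."""

    zone: str
    nodes: list[int]
    centroids: dict[int, tuple[float, float]]
    depths: dict[int, float]
    edges: dict[tuple[int, int], dict[str, float]]  # key (i, j) with i < j

    def edge_key(self, i: int, j: int) -> tuple[int, int]:
        return (i, j) if i < j else (j, i)

    def neighbors(self, i: int) -> list[int]:
        out = []
        for a, b in self.edges:
            if a == i:
                out.append(b)
            elif b == i:
                out.append(a)
        return out


@dataclass
class SpanningTree:
    """Minimum spanning tree (or forest) over a HexGraph."""

    graph: HexGraph
    edges: list[tuple[int, int]]
    total_weight: float

    def adjacency(self) -> dict[int, list[int]]:
        adj: dict[int, list[int]] = {n: [] for n in self.graph.nodes}
        for i, j in self.edges:
            adj[i].append(j)
            adj[j].append(i)
        return adj


@dataclass
class SitePolygon:
    """A contiguous cluster of same-zone hexagons acting as one reef site."""

    site_id: str
    zone: str
    members: list[int]
    geometry: Polygon
    area: float
    centroid: tuple[float, float]

    @property
    def n_hexagons(self) -> int:
        return len(self.members)


def edge_weight(v_norm: float, d_i: float, d_j: float) -> float:
    """Combined proximity/depth-similarity weight of a graph edge."""
    if v_norm < 0:
        raise ValueError("normalized vertex length must be non-negative")
    return float(np.hypot(v_norm, d_i - d_j))


def build_adjacency(hex_map: HexagonMap, zone: str) -> HexGraph:
    """Delaunay adjacency graph of one zone's hexagon centroids.

    With fewer than three hexagons (or degenerate collinear centroids,
    where the triangulation is undefined) the graph falls back to a path
    along the principal axis, which preserves connectivity.
    """
    hexes = hex_map.zone_subset(zone)
    ids = [h.hex_id for h in hexes]
    pts = np.array([h.centroid for h in hexes], dtype=float)
    if len(ids) > 1 and len(np.unique(pts.round(9), axis=0)) != len(ids):
        raise ValueError(f"duplicate hexagon centroids in zone {zone}")
    centroids = {h.hex_id: h.centroid for h in hexes}
    depths = {h.hex_id: h.depth for h in hexes}
    pairs: set[tuple[int, int]] = set()
    if len(ids) >= 3:
        try:
            tri = Delaunay(pts)
            for simplex in tri.simplices:
                for a in range(3):
                    for b in range(a + 1, 3):
                        i, j = ids[simplex[a]], ids[simplex[b]]
                        pairs.add((i, j) if i < j else (j, i))
        except QhullError:
            pairs = _path_pairs(ids, pts)
    elif len(ids) == 2:
        pairs = {(min(ids), max(ids))}
    edges: dict[tuple[int, int], dict[str, float]] = {}
    for i, j in sorted(pairs):
        (xi, yi), (xj, yj) = centroids[i], centroids[j]
        edges[(i, j)] = {"v_raw": float(np.hypot(xi - xj, yi - yj))}
    v_max = max((e["v_raw"] for e in edges.values()), default=1.0)
    v_max = v_max if v_max > 0 else 1.0
    for (i, j), e in edges.items():
        e["v_norm"] = e["v_raw"] / v_max
        e["weight"] = edge_weight(e["v_norm"], depths[i], depths[j])
    return HexGraph(zone=zone, nodes=ids, centroids=centroids, depths=depths, edges=edges)


def _path_pairs(ids: Sequence[int], pts: np.ndarray) -> set[tuple[int, int]]:
    """Chain collinear points along their principal axis."""
    centered = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    order = np.argsort(centered @ vt[0])
    pairs = set()
    for a, b in zip(order[:-1], order[1:]):
        i, j = ids[a], ids[b]
        pairs.add((i, j) if i < j else (j, i))
    return pairs


class _UnionFind:
    def __init__(self, items: Iterable[int]):
        self.parent = {i: i for i in items}

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> bool:
        ri, rj = self.find(i), self.find(j)
        if ri == rj:
            return False
        self.parent[ri] = rj
        return True


def minimum_spanning_tree(graph: HexGraph) -> SpanningTree:
    """Kruskal MST with deterministic (weight, id-pair) tie-breaking.

    On a disconnected graph (not produced by the Delaunay step, but
    admissible) this yields the minimum spanning forest.
    """
    if not graph.nodes:
        return SpanningTree(graph=graph, edges=[], total_weight=0.0)
    ranked = sorted(graph.edges.items(), key=lambda kv: (kv[1]["weight"], kv[0]))
    uf = _UnionFind(graph.nodes)
    chosen: list[tuple[int, int]] = []
    total = 0.0
    for (i, j), attrs in ranked:
        if uf.union(i, j):
            chosen.append((i, j))
            total += attrs["weight"]
    return SpanningTree(graph=graph, edges=chosen, total_weight=total)


def _depth_ssd(members: Iterable[int], depths: dict[int, float]) -> float:
    d = np.array([depths[m] for m in members])
    return float(((d - d.mean()) ** 2).sum()) if d.size else 0.0


def partition_tree(
    tree: SpanningTree,
    graph: HexGraph,
    min_size: int = DEFAULT_MIN_SIZE,
    target_area: float = DEFAULT_TARGET_AREA,
    hex_area: float | None = None,
) -> list[list[int]]:
    """Split the spanning tree into clusters of >= ``min_size`` hexagons.

    Iterative best-edge removal: at each step delete the tree edge whose
    removal most reduces the summed within-cluster depth variance, subject
    to both resulting components having at least ``min_size`` members.
    Splitting stops when no edge is deletable or when the mean cluster
    area has reached ``target_area``.  A connected component smaller than
    ``min_size`` becomes a single cluster.  Returns member-id lists.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    if hex_area is not None and hex_area <= 0:
        raise ValueError("hex_area must be positive")
    if not graph.nodes:
        return []
    adj = tree.adjacency()
    # initial clusters = connected components of the forest
    clusters: list[set[int]] = []
    seen: set[int] = set()
    for n in graph.nodes:
        if n in seen:
            continue
        comp = {n}
        stack = [n]
        while stack:
            cur = stack.pop()
            for nb in adj[cur]:
                if nb not in comp:
                    comp.add(nb)
                    stack.append(nb)
        seen |= comp
        clusters.append(comp)

    tree_edges = set(tree.edges)

    def components_after_cut(cluster: set[int], cut: tuple[int, int]) -> tuple[set[int], set[int]]:
        i, _ = cut
        comp = {i}
        stack = [i]
        while stack:
            cur = stack.pop()
            for nb in adj[cur]:
                e = (cur, nb) if cur < nb else (nb, cur)
                if e == cut or e not in tree_edges:
                    continue
                if nb not in comp:
                    comp.add(nb)
                    stack.append(nb)
        return comp, cluster - comp

    while True:
        if hex_area is not None:
            mean_area = hex_area * len(graph.nodes) / len(clusters)
            if mean_area <= target_area:
                break
        best: tuple[float, tuple[int, int], int, set[int], set[int]] | None = None
        for ci, cluster in enumerate(clusters):
            if len(cluster) < 2 * min_size:
                continue
            base = _depth_ssd(cluster, graph.depths)
            for e in sorted(tree_edges):
                if e[0] not in cluster:
                    continue
                a, b = components_after_cut(cluster, e)
                if len(a) < min_size or len(b) < min_size:
                    continue
                gain = base - _depth_ssd(a, graph.depths) - _depth_ssd(b, graph.depths)
                if best is None or gain > best[0] + 1e-12:
                    best = (gain, e, ci, a, b)
        if best is None:
            break
        _, cut, ci, a, b = best
        tree_edges.discard(cut)
        clusters.pop(ci)
        clusters.extend([a, b])
    return [sorted(c) for c in sorted(clusters, key=min)]


def polygons_to_geometry(
    zone: str, member_lists: Sequence[Sequence[int]], hex_map: HexagonMap
) -> list[SitePolygon]:
    """Materialize clusters as site polygons (union of member hexagon rings)."""
    by_id = {h.hex_id: h for h in hex_map.hexagons}
    sites = []
    for k, members in enumerate(member_lists):
        if not members:
            raise ValueError("empty site")
        rings = [Polygon(by_id[m].vertices) for m in members]
        geom = unary_union(rings)
        c = geom.centroid
        sites.append(
            SitePolygon(
                site_id=f"{zone}-{k:03d}",
                zone=zone,
                members=list(members),
                geometry=geom,
                area=float(geom.area),
                centroid=(float(c.x), float(c.y)),
            )
        )
    return sites


def regionalize(
    hex_map: HexagonMap,
    min_size: int = DEFAULT_MIN_SIZE,
    target_area: float = DEFAULT_TARGET_AREA,
) -> list[SitePolygon]:
    """Full regionalization: per-zone graph -> MST -> partition -> polygons.

    Zones are processed independently; sites never mix zones.
    """
    sites: list[SitePolygon] = []
    zones = sorted({h.zone for h in hex_map.hexagons})
    for zone in zones:
        n_zone = len(hex_map.zone_subset(zone))
        if n_zone == 0:
            continue
        if n_zone == 1:
            clusters = [[hex_map.zone_subset(zone)[0].hex_id]]
        else:
            graph = build_adjacency(hex_map, zone)
            tree = minimum_spanning_tree(graph)
            clusters = partition_tree(
                tree, graph, min_size=min_size, target_area=target_area,
                hex_area=hex_map.hex_area,
            )
        sites.extend(polygons_to_geometry(zone, clusters, hex_map))
    return sites


# ---------------------------------------------------------------------------
# Serialization


def sites_to_geojson(sites: Sequence[SitePolygon], path: str | Path) -> None:
    features = []
    for s in sites:
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(s.geometry),
                "properties": {
                    "site_id": s.site_id,
                    "zone": s.zone,
                    "area": s.area,
                    "n_hexagons": s.n_hexagons,
                    "members": list(s.members),
                },
            }
        )
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": features}))


def sites_from_geojson(path: str | Path) -> list[SitePolygon]:
    fc = json.loads(Path(path).read_text())
    sites = []
    for feat in fc["features"]:
        geom = shape(feat["geometry"])
        p = feat["properties"]
        c = geom.centroid
        sites.append(
            SitePolygon(
                site_id=p["site_id"],
                zone=p["zone"],
                members=[int(m) for m in p.get("members", [])],
                geometry=geom,
                area=float(p["area"]),
                centroid=(float(c.x), float(c.y)),
            )
        )
    return sites


def site_table(sites: Sequence[SitePolygon]) -> pd.DataFrame:
    """Site summary table (one row per site polygon)."""
    return pd.DataFrame(
        {
            "site_id": [s.site_id for s in sites],
            "zone": [s.zone for s in sites],
            "n_hexagons": [s.n_hexagons for s in sites],
            "area_m2": [s.area for s in sites],
            "centroid_x": [s.centroid[0] for s in sites],
            "centroid_y": [s.centroid[1] for s in sites],
        }
    )
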