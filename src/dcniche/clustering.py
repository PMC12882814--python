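"""Dendritic-cell cluster detection from segmented marker detections.

Two rules are implemented.  The primary, section-based rule clusters
detections with a Delaunay triangulation cut at 22.5 μm, merges groups
whose members lie closer than 20 μm border-to-border, and discards
groups whose summed area is below 500 μm².  The secondary, volumetric
rule links 3-D centroids within 20 μm, requires at least 5 members and
caps the cluster diameter at 100 μm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.strtree import STRtree

from .geometry import SurfaceSet, delaunay_graph

__all__ = ["ClusterSet", "filter_detections", "delaunay_cluster", "knn_cluster_3d"]


@dataclass
class ClusterSet:
    """Disjoint groups of detections with their summed area.

    ``members`` holds, per cluster, the sorted list of detection ids;
    ``total_areas`` the summed member areas in μm² (NaN when no areas
    apply, e.g. for pure point clusters); ``labels`` an optional
    vessel-association label per cluster.
    """

    members: list = field(default_factory=list)
    total_areas: list = field(default_factory=list)
    labels: list = field(default_factory=list)

    def __post_init__(self):
        if not self.total_areas:
            self.total_areas = [float("nan")] * len(self.members)
        if not self.labels:
            self.labels = ["unassigned"] * len(self.members)
        if not (len(self.members) == len(self.total_areas) == len(self.labels)):
            raise ValueError("members, total_areas and labels must align")
        seen = set()
        for m in self.members:
            for d in m:
                if d in seen:
                    raise ValueError(f"detection {d!r} belongs to two clusters")
                seen.add(d)

    def __len__(self) -> int:
        return len(self.members)

    def as_partition(self) -> frozenset:
        """The clustering as a canonical set of frozensets (for comparison)."""
        return frozenset(frozenset(m) for m in self.members)


def filter_detections(detections: SurfaceSet, min_area: float = 5.0) -> SurfaceSet:
    """Remove detections smaller than ``min_area`` μm² (boundary kept)."""
    keep = [i for i, a in enumerate(detections.areas) if a >= min_area]
    return detections.subset(keep)


class _UnionFind:
    def __init__(self, n):
        self.parent = list(range(n))

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def delaunay_cluster(
    detections: SurfaceSet,
    edge_len: float = 22.5,
    merge_dist: float = 20.0,
    min_total_area: float = 500.0,
) -> ClusterSet:
    """Cluster detections via Delaunay edges, border merging and an area floor.

    Steps: (1) Delaunay triangulation on detection centroids; (2) keep
    edges with length ≤ ``edge_len``; (3) take connected components;
    (4) merge components containing detections whose border-to-border
    distance is strictly below ``merge_dist``; (5) drop clusters whose
    total area is below ``min_total_area``.
    """
    n = len(detections)
    if n < 2:
        if n == 1 and float(detections.areas.sum()) < min_total_area:
            warnings.warn("single detection cannot reach the minimum cluster area")
        return ClusterSet(members=[], total_areas=[])

    graph = delaunay_graph(detections.centroids)
    uf = _UnionFind(n)
    for u, v, d in graph.edges(data=True):
        if d["length"] <= edge_len:
            uf.union(u, v)

    # transitive border-to-border merge between components
    geoms = np.array(detections.polygons, dtype=object)
    tree = STRtree(list(geoms))
    pairs = tree.query(list(geoms), predicate="dwithin", distance=merge_dist)
    for i, j in zip(*pairs):
        if i >= j:
            continue
        if uf.find(i) == uf.find(j):
            continue
        if float(shapely.distance(geoms[i], geoms[j])) < merge_dist:
            uf.union(int(i), int(j))

    comps: dict = {}
    for i in range(n):
        comps.setdefault(uf.find(i), []).append(i)

    areas = detections.areas
    members, totals = [], []
    for root in sorted(comps):
        idx = comps[root]
        total = float(areas[idx].sum())
        if total >= min_total_area:
            members.append(sorted(detections.ids[i] for i in idx))
            totals.append(total)
    order = np.argsort([str(m[0]) for m in members], kind="stable")
    return ClusterSet(
        members=[members[i] for i in order],
        total_areas=[totals[i] for i in order],
    )


def _diameter(points: np.ndarray, idx: list) -> float:
    sub = points[idx]
    if len(sub) < 2:
        return 0.0
    d2 = ((sub[:, None, :] - sub[None, :, :]) ** 2).sum(-1)
    return float(np.sqrt(d2.max()))


def knn_cluster_3d(
    points: np.ndarray,
    min_size: int = 5,
    neighbor_dist: float = 20.0,
    max_diameter: float = 100.0,
    ids=None,
) -> ClusterSet:
    """Volumetric clustering rule on 3-D centroids.

    Connected components of the ≤ ``neighbor_dist`` proximity graph;
    components with fewer than ``min_size`` members are removed, and
    components wider than ``max_diameter`` are split by repeatedly
    deleting their longest internal link (ties broken lexicographically
    on the endpoint indices) until every component complies.  Fragments
    falling below ``min_size`` during splitting are dropped.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] not in (2, 3):
        raise ValueError("expected (n, 2) or (n, 3) centroids")
    n = len(points)
    if ids is None:
        ids = list(range(n))
    if n == 0:
        return ClusterSet(members=[])

    d2 = ((points[:, None, :] - points[None, :, :]) ** 2).sum(-1)
    dist = np.sqrt(d2)
    edges = {
        (i, j): float(dist[i, j])
        for i in range(n)
        for j in range(i + 1, n)
        if dist[i, j] <= neighbor_dist
    }

    def components(edge_keys, nodes):
        uf = _UnionFind(n)
        for i, j in edge_keys:
            uf.union(i, j)
        comp: dict = {}
        for i in nodes:
            comp.setdefault(uf.find(i), []).append(i)
        return list(comp.values())

    nodes = list(range(n))
    live_edges = dict(edges)
    final: list = []
    queue = [c for c in components(live_edges, nodes)]
    while queue:
        comp = queue.pop()
        if len(comp) < min_size:
            continue
        if _diameter(points, comp) <= max_diameter:
            final.append(comp)
            continue
        comp_set = set(comp)
        comp_edges = {k: v for k, v in live_edges.items() if k[0] in comp_set and k[1] in comp_set}
        # longest link first; deterministic tie-break on endpoints
        kill = max(comp_edges, key=lambda k: (comp_edges[k], -k[0], -k[1]))
        del live_edges[kill]
        sub = components({k: v for k, v in live_edges.items() if k[0] in comp_set and k[1] in comp_set}, comp)
        queue.extend(sub)

    final = [sorted(c) for c in final]
    final.sort(key=lambda c: c[0])
    return ClusterSet(members=[[ids[i] for i in c] for c in final])
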