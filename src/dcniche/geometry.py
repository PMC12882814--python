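"""Shared spatial primitives for tissue-scale niche quantification.

All coordinates are physical micrometres in a 2-D tissue section (the
track module is the only place a z coordinate appears).  Segmented
objects are represented as shapely polygons grouped in a
:class:`SurfaceSet`; cell positions travel as pandas DataFrames with
``x_um`` / ``y_um`` columns ("CellMap"); spatial graphs are undirected
networkx graphs whose edges carry a Euclidean ``length`` attribute.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import Delaunay, QhullError
from shapely.geometry import Polygon
from shapely.ops import unary_union

__all__ = [
    "SurfaceSet",
    "border_distance",
    "overlap_ratio",
    "delaunay_graph",
    "prune_percentile",
    "k_layer_neighborhood",
]


@dataclass
class SurfaceSet:
    """A set of segmented 2-D marker surfaces (polygons) in μm coordinates.

    Parameters
    ----------
    ids
        One identifier per surface (hashable, unique).
    polygons
        Shapely polygons; must be simple (valid) with positive area.
    marker_class
        Marker label per surface (e.g. ``"FSCN1"``, ``"CD31"``).
    """

    ids: list
    polygons: list
    marker_class: list = field(default_factory=list)

    def __post_init__(self):
        self.ids = list(self.ids)
        self.polygons = list(self.polygons)
        if not self.marker_class:
            self.marker_class = [""] * len(self.ids)
        self.marker_class = list(self.marker_class)
        if not (len(self.ids) == len(self.polygons) == len(self.marker_class)):
            raise ValueError("ids, polygons and marker_class must have equal length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("surface ids must be unique")
        for sid, poly in zip(self.ids, self.polygons):
            if not isinstance(poly, Polygon) or not poly.is_valid:
                raise ValueError(f"surface {sid!r}: polygon is not a valid simple polygon")
            if poly.area <= 0:
                raise ValueError(f"surface {sid!r}: polygon has zero area")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def areas(self) -> np.ndarray:
        return np.array([p.area for p in self.polygons], dtype=float)

    @property
    def centroids(self) -> np.ndarray:
        return np.array([[p.centroid.x, p.centroid.y] for p in self.polygons], dtype=float)

    def subset(self, indices) -> "SurfaceSet":
        idx = list(indices)
        return SurfaceSet(
            ids=[self.ids[i] for i in idx],
            polygons=[self.polygons[i] for i in idx],
            marker_class=[self.marker_class[i] for i in idx],
        )

    def index_of(self, sid) -> int:
        return self.ids.index(sid)


def _check_polygon(poly: Polygon, name: str = "polygon") -> None:
    if poly.area <= 0:
        raise ValueError(f"{name} is degenerate (zero area)")


def border_distance(a: Polygon, b: Polygon) -> float:
    """Minimum Euclidean distance between two surface boundaries, in μm.

    Returns 0 when the polygons intersect or touch.  Symmetric in its
    arguments.  Degenerate (zero-area) polygons are rejected.
    """
    _check_polygon(a, "first polygon")
    _check_polygon(b, "second polygon")
    return float(a.distance(b))


def overlap_ratio(a: Polygon, b_set) -> float:
    """Fraction of surface ``a``'s area covered by the union of ``b_set``.

    ``b_set`` may be a :class:`SurfaceSet` or an iterable of polygons.
    The result lies in [0, 1].
    """
    _check_polygon(a, "surface")
    polys = b_set.polygons if isinstance(b_set, SurfaceSet) else list(b_set)
    if not polys:
        return 0.0
    union = unary_union(polys)
    inter = a.intersection(union).area
    return float(min(1.0, inter / a.area))


def _as_points_and_ids(cells):
    """Accept a CellMap DataFrame or an (n, 2) array; return coords + ids."""
    if isinstance(cells, pd.DataFrame):
        pts = cells[["x_um", "y_um"]].to_numpy(dtype=float)
        ids = list(cells["cell_id"]) if "cell_id" in cells.columns else list(cells.index)
    else:
        pts = np.asarray(cells, dtype=float)
        ids = list(range(len(pts)))
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("expected (n, 2) μm coordinates")
    return pts, ids


def delaunay_graph(cells) -> nx.Graph:
    """Delaunay triangulation graph of a point set.

    Nodes are cell ids; undirected edges carry their Euclidean ``length``
    in μm.  Fewer than 3 points, or a collinear set, yields the complete
    graph on the available points.  Exactly coincident coordinates are
    de-duplicated before triangulation; every duplicate id receives the
    same edges as its representative plus a zero-length edge to it, and
    the representative map is stored in ``G.graph["coincident_map"]``.
    """
    pts, ids = _as_points_and_ids(cells)
    G = nx.Graph()
    G.add_nodes_from(ids)
    if len(pts) == 0:
        return G

    uniq, rep_idx, inverse = np.unique(pts, axis=0, return_index=True, return_inverse=True)
    # stable representative: the first occurrence of each coordinate
    order = np.argsort(rep_idx)
    uniq = uniq[order]
    remap = np.empty(len(order), dtype=int)
    remap[order] = np.arange(len(order))
    inverse = remap[inverse]
    rep_of_uniq = [ids[rep_idx[order[u]]] for u in range(len(uniq))]

    def _edge(i, j):
        d = float(np.hypot(*(uniq[i] - uniq[j])))
        G.add_edge(rep_of_uniq[i], rep_of_uniq[j], length=d)

    n_u = len(uniq)
    if n_u < 3:
        for i in range(n_u):
            for j in range(i + 1, n_u):
                _edge(i, j)
    else:
        try:
            tri = Delaunay(uniq)
            pairs = set()
            for simplex in tri.simplices:
                for i in range(3):
                    a, b = sorted((simplex[i], simplex[(i + 1) % 3]))
                    pairs.add((a, b))
            for a, b in pairs:
                _edge(a, b)
        except QhullError:  # collinear input
            for i in range(n_u):
                for j in range(i + 1, n_u):
                    _edge(i, j)

    coincident = {}
    for k, cid in enumerate(ids):
        rep = rep_of_uniq[inverse[k]]
        if cid != rep:
            coincident[cid] = rep
            for nbr, attr in list(G[rep].items()):
                if nbr != cid:
                    G.add_edge(cid, nbr, length=attr["length"])
            G.add_edge(cid, rep, length=0.0)
    G.graph["coincident_map"] = coincident
    return G


def prune_percentile(graph: nx.Graph, percentile: float = 99.0) -> nx.Graph:
    """Drop edges longer than the given percentile of all edge lengths.

    The percentile is the linear-interpolation percentile of the edge
    length vector; edges with length strictly greater than the cutoff
    are removed.  The node set is unchanged.  An edgeless graph is
    returned unchanged with a warning.
    """
    lengths = np.array([d["length"] for _, _, d in graph.edges(data=True)], dtype=float)
    out = graph.copy()
    if lengths.size == 0:
        warnings.warn("prune_percentile: graph has no edges; returned unchanged")
        return out
    cutoff = float(np.percentile(lengths, percentile))
    drop = [(u, v) for u, v, d in out.edges(data=True) if d["length"] > cutoff]
    out.remove_edges_from(drop)
    out.graph["prune_cutoff_um"] = cutoff
    return out


def k_layer_neighborhood(graph: nx.Graph, seeds, k: int) -> set:
    """Cells within ``k`` graph hops ("cell layers") of any seed.

    The seeds themselves are excluded from the result; ``k=0`` therefore
    yields the empty set.  Unknown seed ids are rejected.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    seeds = set(seeds)
    missing = seeds - set(graph.nodes)
    if missing:
        raise KeyError(f"seed ids not in graph: {sorted(missing, key=repr)[:5]}")
    visited = set(seeds)
    frontier = set(seeds)
    out: set = set()
    for _ in range(k):
        nxt = set()
        for u in frontier:
            for v in graph[u]:
                if v not in visited:
                    nxt.add(v)
        if not nxt:
            break
        visited |= nxt
        out |= nxt
        frontier = nxt
    return out - seeds
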