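"""Vessel classification and perivascular niche assignment.

Blood vessels (BV) and lymphatic vessels (LV) are distinguished on
CD31+ surfaces by their overlap with LYVE-1+ surfaces (cutoff 0.01% of
the CD31 area).  DCs and DC clusters are then assigned to the nearest
vessel class within an association cutoff — 20 μm border-to-border in
mouse sections, with 50 μm border / 100 μm centroid presets for the
human imaging dialects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Point
from shapely.ops import unary_union

from .clustering import ClusterSet
from .geometry import SurfaceSet, overlap_ratio

__all__ = [
    "VesselSet",
    "AssociationConfig",
    "classify_vessels",
    "associate_cells",
    "associate_clusters",
    "ccl19_coverage",
    "ccl21_membership",
    "vessel_dc_load",
]


@dataclass
class VesselSet:
    """Classified vessel surfaces.

    ``classes`` holds ``"BV"`` or ``"LV"`` per vessel; ``subtype`` an
    optional externally supplied venous/arterial/capillary label;
    ``ccl19_covered`` an optional per-vessel coverage flag.
    """

    surfaces: SurfaceSet
    classes: list
    subtype: Optional[list] = None
    ccl19_covered: Optional[list] = None

    def __post_init__(self):
        self.classes = list(self.classes)
        if len(self.classes) != len(self.surfaces):
            raise ValueError("one class per vessel required")
        bad = sorted({c for c in self.classes} - {"BV", "LV"})
        if bad:
            raise ValueError(f"vessel class must be BV or LV, got {bad}")

    def __len__(self) -> int:
        return len(self.surfaces)

    def of_class(self, cls: str) -> list:
        return [p for p, c in zip(self.surfaces.polygons, self.classes) if c == cls]


@dataclass
class AssociationConfig:
    """Distance rule for vessel association.

    ``vessel_cutoff``: DCs farther than this from every vessel are
    non-vessel-associated.  ``cluster_area_fraction``: minimum fraction
    of a cluster's area that must lie within the cutoff of a vessel
    class.  ``distance_mode``: ``"border"`` (border-to-border) or
    ``"centroid"`` (centroid-to-centroid).
    """

    vessel_cutoff: float = 20.0
    cluster_area_fraction: float = 0.5
    distance_mode: str = "border"

    def __post_init__(self):
        if self.vessel_cutoff <= 0:
            raise ValueError("vessel_cutoff must be positive")
        if not (0 < self.cluster_area_fraction <= 1):
            raise ValueError("cluster_area_fraction must lie in (0, 1]")
        if self.distance_mode not in ("border", "centroid"):
            raise ValueError("distance_mode must be 'border' or 'centroid'")

    @classmethod
    def mouse(cls) -> "AssociationConfig":
        return cls(vessel_cutoff=20.0, distance_mode="border")

    @classmethod
    def human_fast(cls) -> "AssociationConfig":
        """FAST cyclic-imaging dialect: 50 μm border-to-border."""
        return cls(vessel_cutoff=50.0, distance_mode="border")

    @classmethod
    def human_multispectral(cls) -> "AssociationConfig":
        """Multispectral-imaging dialect: 100 μm centroid-to-centroid."""
        return cls(vessel_cutoff=100.0, distance_mode="centroid")


def classify_vessels(cd31: SurfaceSet, lyve1: SurfaceSet, ratio_cutoff: float = 0.0001) -> VesselSet:
    """Type CD31+ surfaces as BV or LV by LYVE-1 overlap ratio.

    Overlap ratio strictly below ``ratio_cutoff`` (default 0.01%) → BV;
    at or above → LV.
    """
    lyve_union = unary_union(lyve1.polygons) if len(lyve1) else None
    classes = []
    for poly in cd31.polygons:
        if lyve_union is None:
            ratio = 0.0
        else:
            ratio = poly.intersection(lyve_union).area / poly.area
        classes.append("BV" if ratio < ratio_cutoff else "LV")
    return VesselSet(surfaces=cd31, classes=classes)


def _dc_geometries(dcs):
    """DCs as (ids, geometries): SurfaceSet polygons or CellMap points."""
    if isinstance(dcs, SurfaceSet):
        return list(dcs.ids), list(dcs.polygons)
    if isinstance(dcs, pd.DataFrame):
        ids = list(dcs["cell_id"])
        geoms = [Point(x, y) for x, y in dcs[["x_um", "y_um"]].to_numpy(float)]
        return ids, geoms
    raise TypeError("dcs must be a SurfaceSet or a CellMap DataFrame")


def _min_dist(geom, vessel_polys, mode: str) -> float:
    if not vessel_polys:
        return float("inf")
    if mode == "border":
        return min(float(geom.distance(v)) for v in vessel_polys)
    c = geom.centroid
    return min(float(c.distance(v.centroid)) for v in vessel_polys)


def associate_cells(dcs, vessels: VesselSet, cfg: AssociationConfig = None) -> pd.DataFrame:
    """Assign each DC to BV, LV or none.

    A DC farther than the cutoff from every vessel is non-vessel-
    associated (``none``); otherwise it takes the class of the nearer
    vessel (exact ties resolved to BV).  When one vessel class is
    entirely absent the remaining class wins by default; this is
    flagged in ``result.attrs["missing_classes"]``.

    Returns a DataFrame with ``dc_id``, ``d_bv``, ``d_lv``, ``label``.
    """
    cfg = cfg or AssociationConfig()
    ids, geoms = _dc_geometries(dcs)
    bv = vessels.of_class("BV")
    lv = vessels.of_class("LV")
    missing = [c for c, ps in (("BV", bv), ("LV", lv)) if not ps]

    rows = []
    for did, g in zip(ids, geoms):
        d_bv = _min_dist(g, bv, cfg.distance_mode)
        d_lv = _min_dist(g, lv, cfg.distance_mode)
        if min(d_bv, d_lv) > cfg.vessel_cutoff:
            label = "none"
        elif d_bv <= d_lv:
            label = "BV"
        else:
            label = "LV"
        rows.append((did, d_bv, d_lv, label))
    out = pd.DataFrame(rows, columns=["dc_id", "d_bv", "d_lv", "label"])
    out.attrs["missing_classes"] = missing
    out.attrs["config"] = cfg
    return out


def associate_clusters(
    clusters: ClusterSet,
    detections: SurfaceSet,
    vessels: VesselSet,
    cfg: AssociationConfig = None,
) -> pd.DataFrame:
    """Label each DC cluster BV / LV / unassociated by proximal area.

    A cluster is associated with a vessel class when at least
    ``cfg.cluster_area_fraction`` (default 50%) of its member area lies
    within ``cfg.vessel_cutoff`` of a vessel of that class.  Dual
    qualification resolves to the class with the larger proximal area
    (exact tie → BV).
    """
    cfg = cfg or AssociationConfig()
    bv = vessels.of_class("BV")
    lv = vessels.of_class("LV")
    idx = {sid: i for i, sid in enumerate(detections.ids)}
    areas = detections.areas

    rows = []
    for ci, members in enumerate(clusters.members):
        a_bv = a_lv = total = 0.0
        for sid in members:
            i = idx[sid]
            poly = detections.polygons[i]
            total += areas[i]
            if _min_dist(poly, bv, cfg.distance_mode) <= cfg.vessel_cutoff:
                a_bv += areas[i]
            if _min_dist(poly, lv, cfg.distance_mode) <= cfg.vessel_cutoff:
                a_lv += areas[i]
        f_bv = a_bv / total if total else 0.0
        f_lv = a_lv / total if total else 0.0
        if f_bv >= cfg.cluster_area_fraction and f_lv >= cfg.cluster_area_fraction:
            label = "BV" if a_bv >= a_lv else "LV"
        elif f_bv >= cfg.cluster_area_fraction:
            label = "BV"
        elif f_lv >= cfg.cluster_area_fraction:
            label = "LV"
        else:
            label = "none"
        rows.append((ci, total, f_bv, f_lv, label))
    return pd.DataFrame(
        rows, columns=["cluster_id", "total_area_um2", "frac_near_bv", "frac_near_lv", "label"]
    )


def ccl19_coverage(vessels: VesselSet, ccl19: SurfaceSet) -> dict:
    """Flag vessels covered by Ccl19+ surfaces and summarize BV areas.

    A vessel is covered as soon as its overlap ratio with the Ccl19+
    surfaces is strictly positive.  The summary normalizes summed
    covered and non-covered BV areas to the total BV area (they sum to
    1 whenever any BV exists).
    """
    flags, ratios = [], []
    for poly in vessels.surfaces.polygons:
        r = overlap_ratio(poly, ccl19)
        ratios.append(r)
        flags.append(r > 0)
    areas = vessels.surfaces.areas
    is_bv = np.array([c == "BV" for c in vessels.classes])
    cov = np.array(flags)
    bv_total = float(areas[is_bv].sum())
    covered_area = float(areas[is_bv & cov].sum())
    uncovered_area = float(areas[is_bv & ~cov].sum())
    return {
        "covered": flags,
        "overlap_ratios": ratios,
        "bv_covered_area_fraction": covered_area / bv_total if bv_total else float("nan"),
        "bv_uncovered_area_fraction": uncovered_area / bv_total if bv_total else float("nan"),
    }


def ccl21_membership(clusters: ClusterSet, detections: SurfaceSet, regions: SurfaceSet) -> list:
    """Per-cluster: does any member centroid fall in a CCL21+ region?

    The membership rule is centroid-to-border distance 0, i.e. the
    member centroid lies inside or on a region boundary.
    """
    region_union = unary_union(regions.polygons) if len(regions) else None
    idx = {sid: i for i, sid in enumerate(detections.ids)}
    out = []
    for members in clusters.members:
        inside = False
        if region_union is not None:
            for sid in members:
                c = detections.polygons[idx[sid]].centroid
                if region_union.covers(c):
                    inside = True
                    break
        out.append(inside)
    return out


def vessel_dc_load(
    vessel, dcs: SurfaceSet, cutoff: float = 20.0, cluster_area: float = 500.0
) -> dict:
    """Total DC area within ``cutoff`` of one vessel, and its niche label.

    Sums the areas of DC surfaces whose border-to-border distance to the
    vessel is at most ``cutoff``; the vessel is "cluster-associated"
    when that sum reaches ``cluster_area`` μm².
    """
    poly = vessel.polygons[0] if isinstance(vessel, SurfaceSet) else vessel
    proximal = [
        i for i, dc in enumerate(dcs.polygons) if float(shapely.distance(poly, dc)) <= cutoff
    ]
    total = float(dcs.areas[proximal].sum()) if proximal else 0.0
    return {
        "total_dc_area_um2": total,
        "cluster_associated": total >= cluster_area,
        "n_proximal": len(proximal),
    }
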