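"""Nearest-distance statistics between cell classes.

These summaries profile the composition of DC niches: nearest distance
from each DC to every other cell class, the fraction of DCs with a Treg
within 50 μm, DC–CD8 niches with or without Tregs within 100 μm, and
the vessel-site distribution of DC–Treg contacts.
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np
import pandas as pd
import shapely

from .geometry import SurfaceSet
from .vessels import AssociationConfig, VesselSet, associate_cells

__all__ = [
    "nearest_by_type",
    "fraction_with_neighbor",
    "niche_treg_status",
    "contact_by_vessel_class",
]


def _pairwise_dist(src: pd.DataFrame, tgt: pd.DataFrame, mode: str) -> np.ndarray:
    a = src[["x_um", "y_um"]].to_numpy(float)
    b = tgt[["x_um", "y_um"]].to_numpy(float)
    d = np.sqrt(((a[:, None, :] - b[None, :, :]) ** 2).sum(-1))
    if mode == "border":
        for df in (src, tgt):
            if "radius_um" not in df.columns:
                raise ValueError("border mode requires a radius_um column")
        d = d - src["radius_um"].to_numpy(float)[:, None] - tgt["radius_um"].to_numpy(float)[None, :]
        d = np.maximum(d, 0.0)
    return d


def nearest_by_type(
    cells: pd.DataFrame,
    source_type: str,
    target_types,
    mode: str = "centroid",
) -> pd.DataFrame:
    """Nearest distance (and arg-min id) from each source cell to each target type.

    Distances are squared internally with a final square root.  A cell
    is never its own nearest target when source and target types
    coincide.  Target types absent from the table yield NaN distance
    columns, listed in ``result.attrs["absent_types"]``.
    """
    if mode not in ("centroid", "border"):
        raise ValueError("mode must be 'centroid' or 'border'")
    src = cells[cells["cell_type"] == source_type]
    if src.empty:
        raise ValueError(f"no cells of source type {source_type!r}")
    out = pd.DataFrame({"cell_id": src["cell_id"].to_numpy()})
    absent = []
    for t in target_types:
        tgt = cells[cells["cell_type"] == t]
        if tgt.empty:
            out[f"d_{t}"] = np.nan
            out[f"id_{t}"] = None
            absent.append(t)
            continue
        d = _pairwise_dist(src, tgt, mode)
        same = src["cell_id"].to_numpy()[:, None] == tgt["cell_id"].to_numpy()[None, :]
        d = np.where(same, np.inf, d)
        j = d.argmin(axis=1)
        dmin = d[np.arange(len(src)), j]
        dmin = np.where(np.isfinite(dmin), dmin, np.nan)
        out[f"d_{t}"] = dmin
        out[f"id_{t}"] = tgt["cell_id"].to_numpy()[j]
        out.loc[out[f"d_{t}"].isna(), f"id_{t}"] = None
    out.attrs["absent_types"] = absent
    return out


def fraction_with_neighbor(
    cells: pd.DataFrame,
    source_type: str,
    target_type: str,
    radius: float = 50.0,
    mode: str = "centroid",
) -> float:
    """Fraction of source cells with a target cell strictly closer than ``radius``.

    Returns NaN (with a warning) when there are no source cells.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if (cells["cell_type"] == source_type).sum() == 0:
        warnings.warn(f"no {source_type!r} cells; fraction undefined")
        return float("nan")
    near = nearest_by_type(cells, source_type, [target_type], mode=mode)
    d = near[f"d_{target_type}"].to_numpy(float)
    return float(np.mean(np.nan_to_num(d, nan=np.inf) < radius))


def niche_treg_status(
    cells: pd.DataFrame,
    dc_type: str,
    cd8_type: str,
    treg_type: str,
    contact: float = 5.0,
    treg_radius: float = 100.0,
    mode: str = "centroid",
) -> dict:
    """DC–CD8 niches with vs without a Treg in their proximity.

    A niche is a DC with at least one CD8 cell within ``contact``
    (inclusive, the static interaction rule); it is Treg-proximal when
    at least one Treg lies strictly within ``treg_radius`` of the DC.
    The two frequencies sum to 1 over niches; with no niches both are
    NaN and flagged.
    """
    near = nearest_by_type(cells, dc_type, [cd8_type, treg_type], mode=mode)
    d_cd8 = np.nan_to_num(near[f"d_{cd8_type}"].to_numpy(float), nan=np.inf)
    d_treg = np.nan_to_num(near[f"d_{treg_type}"].to_numpy(float), nan=np.inf)
    is_niche = d_cd8 <= contact
    n = int(is_niche.sum())
    if n == 0:
        warnings.warn("no DC-CD8 niches found; frequencies undefined")
        return {"n_niches": 0, "frac_with_treg": float("nan"), "frac_without_treg": float("nan")}
    with_treg = d_treg[is_niche] < treg_radius
    return {
        "n_niches": n,
        "frac_with_treg": float(with_treg.mean()),
        "frac_without_treg": float(1.0 - with_treg.mean()),
    }


def contact_by_vessel_class(
    dcs,
    tregs,
    vessels: VesselSet,
    contact: float = 5.0,
    cfg: Optional[AssociationConfig] = None,
) -> dict:
    """Vessel-site distribution of DCs in contact with a Treg.

    Restricts to DCs whose border distance to the nearest Treg is at
    most ``contact`` (≤ 5 μm static interaction rule), then reports the
    distribution of their vessel-association labels {BV, LV, none}
    (fractions sum to 1).  ``dcs``/``tregs`` may be SurfaceSets or
    CellMap point tables.  With no contacting DCs the fractions are NaN.
    """
    cfg = cfg or AssociationConfig()
    assoc = associate_cells(dcs, vessels, cfg)

    def geoms(obj):
        if isinstance(obj, SurfaceSet):
            return list(obj.polygons)
        return [shapely.Point(x, y) for x, y in obj[["x_um", "y_um"]].to_numpy(float)]

    dg, tg = geoms(dcs), geoms(tregs)
    contacting = []
    for i, g in enumerate(dg):
        if tg and min(float(g.distance(t)) for t in tg) <= contact:
            contacting.append(i)
    n = len(contacting)
    if n == 0:
        warnings.warn("no DCs in contact with a Treg; fractions undefined")
        return {"n_contacting": 0, "BV": float("nan"), "LV": float("nan"), "none": float("nan")}
    labels = assoc["label"].to_numpy()[contacting]
    return {
        "n_contacting": n,
        **{c: float((labels == c).mean()) for c in ("BV", "LV", "none")},
    }
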