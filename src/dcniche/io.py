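"""Readers, writers, configuration and the three pipeline workflows.

File contracts
--------------
CellMap CSV       ``cell_id, sample_id, x_um, y_um, cell_type[, gene_*...]``
SurfaceSet GeoJSON FeatureCollection; feature properties
                  ``{surface_id, marker_class, area_um2}``
Track CSV         ``object_id, class, frame, t_s, x_um, y_um, z_um, radius_um``
Config            YAML or JSON mapping; see ``run_pipeline``.

``run_pipeline`` executes one of three workflows — ``niche`` (detection
filtering, Delaunay clustering, vessel typing and association),
``enrichment`` (spatial graph, nh_sum, permutation enrichment) or
``tracks`` (contact episodes, cumulative interactions, speeds) — and
writes tidy CSV/JSON results plus a provenance record (config hash,
seed, version).  Identical config and seed give byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import mapping, shape

from . import __version__
from .clustering import delaunay_cluster, filter_detections
from .enrichment import nh_sum, permutation_enrichment
from .geometry import SurfaceSet, delaunay_graph, prune_percentile
from .tracks import cumulative_interactions, detect_contacts, track_speed, validate_tracks
from .vessels import AssociationConfig, VesselSet, associate_cells, associate_clusters, classify_vessels

__all__ = [
    "read_cells",
    "write_cells",
    "read_surfaces",
    "write_surfaces",
    "read_tracks",
    "write_tracks",
    "read_vessels",
    "write_vessels",
    "load_config",
    "run_pipeline",
]

_CELL_COLUMNS = ["cell_id", "sample_id", "x_um", "y_um", "cell_type"]


def read_cells(path) -> pd.DataFrame:
    """Load and validate a CellMap CSV."""
    df = pd.read_csv(path)
    missing = [c for c in _CELL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory columns {missing}")
    for col in ("x_um", "y_um"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any() or df[col].isna().any():
            rows = df.index[bad | df[col].isna()].tolist()[:5]
            raise ValueError(f"{path}: non-numeric or missing {col} at rows {rows}")
        df[col] = df[col].astype(float)
    dup = df["cell_id"][df["cell_id"].duplicated()]
    if not dup.empty:
        raise ValueError(f"{path}: duplicated cell_id {dup.iloc[0]!r}")
    return df


def write_cells(cells: pd.DataFrame, path) -> None:
    cells.to_csv(path, index=False)


def write_surfaces(surfaces: SurfaceSet, path, extra_properties: dict = None) -> None:
    """Write a SurfaceSet as a GeoJSON FeatureCollection."""
    features = []
    for i, (sid, poly, cls) in enumerate(
        zip(surfaces.ids, surfaces.polygons, surfaces.marker_class)
    ):
        props = {"surface_id": sid, "marker_class": cls, "area_um2": poly.area}
        if extra_properties:
            props.update({k: v[i] for k, v in extra_properties.items()})
        features.append({"type": "Feature", "geometry": mapping(poly), "properties": props})
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_surfaces(path, area_tolerance: float = 0.01):
    """Load a GeoJSON FeatureCollection as a SurfaceSet (+ extra properties).

    The stored ``area_um2`` is checked against the polygon area to the
    given relative tolerance.  Returns ``(SurfaceSet, properties)``
    where ``properties`` is a DataFrame of all feature properties.
    """
    with open(path) as fh:
        gj = json.load(fh)
    ids, polys, classes, props = [], [], [], []
    for feat in gj.get("features", []):
        poly = shape(feat["geometry"])
        p = feat.get("properties", {})
        sid = p.get("surface_id")
        stored = p.get("area_um2")
        if stored is not None and poly.area > 0:
            if abs(stored - poly.area) / poly.area > area_tolerance:
                raise ValueError(
                    f"{path}: surface {sid!r} stored area {stored:.3f} inconsistent with "
                    f"polygon area {poly.area:.3f}"
                )
        ids.append(sid)
        polys.append(poly)
        classes.append(p.get("marker_class", ""))
        props.append(p)
    return SurfaceSet(ids, polys, classes), pd.DataFrame(props)


def write_vessels(vessels: VesselSet, path) -> None:
    extra = {"vessel_class": list(vessels.classes)}
    if vessels.ccl19_covered is not None:
        extra["ccl19_covered"] = [bool(v) for v in vessels.ccl19_covered]
    if vessels.subtype is not None:
        extra["subtype"] = list(vessels.subtype)
    write_surfaces(vessels.surfaces, path, extra_properties=extra)


def read_vessels(path) -> VesselSet:
    surfaces, props = read_surfaces(path)
    if "vessel_class" not in props.columns:
        raise ValueError(f"{path}: vessel GeoJSON needs a 'vessel_class' property (BV/LV)")
    return VesselSet(
        surfaces=surfaces,
        classes=list(props["vessel_class"]),
        ccl19_covered=list(props["ccl19_covered"]) if "ccl19_covered" in props.columns else None,
        subtype=list(props["subtype"]) if "subtype" in props.columns else None,
    )


def read_tracks(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    return validate_tracks(df)


def write_tracks(tracks: pd.DataFrame, path) -> None:
    tracks.to_csv(path, index=False)


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, dict):
        return dict(path_or_dict)
    text = Path(path_or_dict).read_text()
    return yaml.safe_load(text)


def _config_hash(config: dict) -> str:
    canonical = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()


def _provenance(config: dict, out_dir: Path) -> None:
    record = {
        "config": config,
        "config_sha256": _config_hash(config),
        "seed": config.get("seed"),
        "dcniche_version": __version__,
    }
    (out_dir / "provenance.json").write_text(json.dumps(record, indent=2, sort_keys=True, default=str))


def _assoc_cfg(params: dict) -> AssociationConfig:
    return AssociationConfig(
        vessel_cutoff=params.get("vessel_cutoff", 20.0),
        cluster_area_fraction=params.get("cluster_area_fraction", 0.5),
        distance_mode=params.get("distance_mode", "border"),
    )


def _run_niche(config: dict, out_dir: Path) -> dict:
    params = config.get("params", {})
    detections, _ = read_surfaces(config["inputs"]["detections"])
    vessel_path = config["inputs"].get("vessels")
    if vessel_path:
        vessels = read_vessels(vessel_path)
    else:
        cd31, _ = read_surfaces(config["inputs"]["cd31"])
        lyve1, _ = read_surfaces(config["inputs"]["lyve1"])
        vessels = classify_vessels(cd31, lyve1, params.get("lyve1_ratio_cutoff", 0.0001))
    kept = filter_detections(detections, params.get("min_area", 5.0))
    clusters = delaunay_cluster(
        kept,
        edge_len=params.get("edge_len", 22.5),
        merge_dist=params.get("merge_dist", 20.0),
        min_total_area=params.get("min_total_area", 500.0),
    )
    cfg = _assoc_cfg(params)
    cell_assoc = associate_cells(kept, vessels, cfg)
    cluster_assoc = associate_clusters(clusters, kept, vessels, cfg)
    membership = pd.DataFrame(
        [
            (ci, sid)
            for ci, members in enumerate(clusters.members)
            for sid in members
        ],
        columns=["cluster_id", "detection_id"],
    )
    cell_assoc.to_csv(out_dir / "dc_association.csv", index=False)
    cluster_assoc.to_csv(out_dir / "cluster_association.csv", index=False)
    membership.to_csv(out_dir / "cluster_members.csv", index=False)
    counts = cell_assoc["label"].value_counts()
    summary = {
        "n_detections": len(detections),
        "n_kept": len(kept),
        "n_clusters": len(clusters),
        "dc_fraction_bv": float(counts.get("BV", 0)) / max(len(kept), 1),
        "dc_fraction_lv": float(counts.get("LV", 0)) / max(len(kept), 1),
        "dc_fraction_none": float(counts.get("none", 0)) / max(len(kept), 1),
    }
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary


def _run_enrichment(config: dict, out_dir: Path) -> dict:
    params = config.get("params", {})
    cells = read_cells(config["inputs"]["cells"])
    graph = prune_percentile(delaunay_graph(cells), params.get("prune_percentile", 99.0))
    k = params.get("k_layers", 5)
    Y = nh_sum(cells, graph, k=k)
    Y.to_csv(out_dir / "neighborhood_matrix.csv")
    selected_type = params.get("selected_type")
    target_type = params.get("target_type")
    summary = {"n_cells": len(cells), "k_layers": k}
    if selected_type and target_type:
        selected = set(cells.loc[cells["cell_type"] == selected_type, "cell_id"])
        res = permutation_enrichment(
            cells,
            graph,
            selected,
            target_type,
            k=k,
            n_perm=params.get("n_perm", 1000),
            seed=config.get("seed"),
        )
        tidy = pd.DataFrame(
            {
                "sample_id": cells["sample_id"].iloc[0] if len(cells) else "",
                "group": selected_type,
                "type": target_type,
                "statistic": ["observed", "baseline", "score", "p_value"],
                "value": [res.observed, res.baseline, res.score, res.p_value],
            }
        )
        tidy.to_csv(out_dir / "enrichment.csv", index=False)
        (out_dir / "null_scores.json").write_text(
            json.dumps({"null_scores": [None if np.isnan(v) else v for v in res.null_scores]})
        )
        summary.update(score=res.score, p_value=res.p_value)
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary


def _run_tracks(config: dict, out_dir: Path) -> dict:
    params = config.get("params", {})
    tracks = read_tracks(config["inputs"]["tracks"])
    contacts = detect_contacts(
        tracks,
        threshold=params.get("contact", 5.0),
        gap_tolerance=params.get("gap_tolerance", 0),
    )
    cumulative = cumulative_interactions(tracks, radius=params.get("interaction_radius", 20.0))
    speeds = track_speed(tracks)
    contacts.to_csv(out_dir / "contacts.csv", index=False)
    cumulative.to_csv(out_dir / "cumulative_interactions.csv", index=False)
    speeds.rename_axis("object_id").to_csv(out_dir / "track_speeds.csv")
    summary = {
        "n_episodes": int(len(contacts)),
        "median_duration_min": float(contacts["duration_min"].median()) if len(contacts) else None,
        "mean_speed_um_per_s": float(np.nanmean(speeds.to_numpy())) if len(speeds) else None,
    }
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary


_WORKFLOWS = {"niche": _run_niche, "enrichment": _run_enrichment, "tracks": _run_tracks}


def run_pipeline(config) -> dict:
    """Execute one named workflow from a config mapping (or YAML/JSON path).

    The config must carry ``workflow`` (niche | enrichment | tracks),
    ``inputs`` (paths per workflow), ``out_dir``, and optionally
    ``params`` and ``seed``.  Unknown workflows or parameters are
    rejected before any computation.
    """
    config = load_config(config)
    workflow = config.get("workflow")
    if workflow not in _WORKFLOWS:
        raise ValueError(f"unknown workflow {workflow!r}; expected one of {sorted(_WORKFLOWS)}")
    known = {
        "niche": {"min_area", "edge_len", "merge_dist", "min_total_area", "vessel_cutoff",
                  "cluster_area_fraction", "distance_mode", "lyve1_ratio_cutoff"},
        "enrichment": {"prune_percentile", "k_layers", "n_perm", "selected_type", "target_type"},
        "tracks": {"contact", "gap_tolerance", "interaction_radius"},
    }[workflow]
    unknown = set(config.get("params", {})) - known
    if unknown:
        raise ValueError(f"unknown parameters for workflow {workflow!r}: {sorted(unknown)}")
    if "out_dir" not in config:
        raise ValueError("config must name an out_dir")
    out_dir = Path(config["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    summary = _WORKFLOWS[workflow](config, out_dir)
    _provenance(config, out_dir)
    return summary
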