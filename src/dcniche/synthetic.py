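"""Synthetic scenes, expression matrices and tracks with planted truth.

Every downstream stage of the pipeline is validated against data whose
ground truth is known by construction:

* ``generate_scene`` — a 2-D marked point pattern with capsule-shaped
  vessel surfaces (blood and lymphatic), disk-shaped DC detections of
  which a configured fraction is planted perivascularly (surface gap to
  an anchor blood vessel within the association cutoff), plus bystander
  Tregs and other cells kept clear of all vessels.
* ``generate_tracks`` — 3-D random-walk tracks for DC and Treg objects
  with planted contact episodes during which the pair's sphere surface
  distance is held below the contact threshold, and outside which it
  exceeds the threshold by a wide margin.
* ``generate_expression`` — per-cell expression with a positive
  subpopulation shifted upward on the signature genes, producing the
  bimodal signature-score structure the classifier consumes.

All randomness flows from one seeded generator per call; fixed seeds
give byte-identical outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point

from .geometry import SurfaceSet
from .vessels import VesselSet

__all__ = [
    "SceneConfig",
    "TrackConfig",
    "ExpressionConfig",
    "Scene",
    "generate_scene",
    "generate_tracks",
    "generate_expression",
    "sample_episodes",
]

# geometric slack (μm) keeping planted labels unambiguous for the rules
_GAP_MARGIN = 2.0


@dataclass
class SceneConfig:
    """Layout of a synthetic tumor-section scene (all lengths in μm)."""

    field_width: float = 1000.0
    field_height: float = 1000.0
    n_vessels_bv: int = 4
    n_vessels_lv: int = 2
    vessel_radius_range: Tuple[float, float] = (5.0, 12.0)
    vessel_length_range: Tuple[float, float] = (30.0, 80.0)
    n_dc: int = 100
    n_treg: int = 50
    n_other: int = 100
    perivascular_fraction: float = 0.5
    perilymphatic_fraction: float = 0.0
    cluster_dispersion: float = 10.0
    ccl19_cover_fraction: float = 0.5
    dc_radius: float = 4.0
    association_cutoff: float = 20.0
    sample_id: str = "S0"
    seed: int = 0

    def __post_init__(self):
        if self.field_width <= 0 or self.field_height <= 0:
            raise ValueError("field dimensions must be positive (zero-area field rejected)")
        for name in ("n_vessels_bv", "n_vessels_lv", "n_dc", "n_treg", "n_other"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("perivascular_fraction", "perilymphatic_fraction", "ccl19_cover_fraction"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.perivascular_fraction + self.perilymphatic_fraction > 1:
            raise ValueError("planted vessel fractions exceed 1")


@dataclass
class TrackConfig:
    """Layout of a synthetic time-lapse recording."""

    n_dc_tracks: int = 5
    n_treg_tracks: int = 10
    n_frames: int = 40
    frame_interval: float = 90.0  # seconds
    planted_episodes: List[Tuple] = field(default_factory=list)  # (dc, treg, start, end)
    motility_sd: float = 1.5      # μm per frame
    object_radius: float = 5.0
    contact_gap: float = 2.0      # surface gap held during episodes (< threshold)
    seed: int = 0

    def __post_init__(self):
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        for dc, tr, start, end in self.planted_episodes:
            if not (0 <= start <= end < self.n_frames):
                raise ValueError(f"episode ({dc}, {tr}, {start}, {end}) outside [0, n_frames)")
            if not (0 <= dc < self.n_dc_tracks and 0 <= tr < self.n_treg_tracks):
                raise ValueError(f"episode ({dc}, {tr}) references an unknown track")


@dataclass
class ExpressionConfig:
    """Layout of a synthetic expression matrix with a planted positive class."""

    n_cells: int = 2000
    n_genes: int = 200
    signature_genes: List[str] = field(default_factory=lambda: [f"gene_{i:03d}" for i in range(10)])
    positive_fraction: float = 0.3
    effect_size: float = 3.0
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.positive_fraction <= 1):
            raise ValueError("positive_fraction must lie in [0, 1]")
        universe = {f"gene_{i:03d}" for i in range(self.n_genes)}
        named = {g if g.startswith("gene_") else f"gene_{g}" for g in self.signature_genes}
        if not named <= universe:
            raise ValueError("signature_genes must be a subset of the gene universe")


@dataclass
class Scene:
    """A generated scene plus its planted ground truth."""

    cells: pd.DataFrame
    dc_surfaces: SurfaceSet
    vessels: VesselSet
    ccl19: SurfaceSet
    truth: dict


def _capsule(rng, cfg: SceneConfig, margin: float):
    w, h = cfg.field_width, cfg.field_height
    length = rng.uniform(*cfg.vessel_length_range)
    radius = rng.uniform(*cfg.vessel_radius_range)
    theta = rng.uniform(0, np.pi)
    cx = rng.uniform(margin, max(w - margin, margin))
    cy = rng.uniform(margin, max(h - margin, margin))
    dx, dy = 0.5 * length * np.cos(theta), 0.5 * length * np.sin(theta)
    axis = LineString([(cx - dx, cy - dy), (cx + dx, cy + dy)])
    return axis.buffer(radius, quad_segs=16), axis, radius


def generate_scene(config: SceneConfig) -> Scene:
    """Generate a scene with planted perivascular DC structure.

    Vessels are capsules (segment + radius) kept mutually separated by
    more than twice the association cutoff, so a DC planted within the
    cutoff of its anchor vessel is unambiguously closest to it.
    Background cells are rejection-sampled farther than the cutoff plus
    a margin from every vessel, so their planted label is ``none``.
    """
    rng = np.random.default_rng(config.seed)
    cutoff = config.association_cutoff
    margin = max(config.vessel_length_range[1] / 2 + config.vessel_radius_range[1], 1.0)

    n_vessels = config.n_vessels_bv + config.n_vessels_lv
    polygons, axes = [], []
    min_gap = 2 * cutoff + 3 * _GAP_MARGIN + 2 * config.dc_radius
    attempts = 0
    while len(polygons) < n_vessels:
        attempts += 1
        if attempts > 2000 * max(n_vessels, 1):
            raise RuntimeError("could not place vessels with the required separation; "
                               "enlarge the field or reduce vessel count")
        poly, axis, _ = _capsule(rng, config, margin)
        if all(poly.distance(p) > min_gap for p in polygons):
            polygons.append(poly)
            axes.append(axis)

    classes = ["BV"] * config.n_vessels_bv + ["LV"] * config.n_vessels_lv
    vessel_ids = [f"V{i:03d}" for i in range(n_vessels)]
    vessels = VesselSet(
        surfaces=SurfaceSet(vessel_ids, polygons, ["CD31"] * n_vessels),
        classes=classes,
    )

    # Ccl19 shells on a fraction of the blood vessels: an annulus
    # straddling the vessel boundary, so the overlap ratio is positive.
    bv_idx = [i for i, c in enumerate(classes) if c == "BV"]
    n_cover = int(round(config.ccl19_cover_fraction * len(bv_idx)))
    covered_idx = set(bv_idx[:n_cover])
    ccl19_polys, ccl19_ids = [], []
    for i in sorted(covered_idx):
        ring = polygons[i].buffer(1.5).difference(polygons[i].buffer(-1.5))
        ccl19_polys.append(ring)
        ccl19_ids.append(f"C{i:03d}")
    ccl19 = SurfaceSet(ccl19_ids, ccl19_polys, ["Ccl19"] * len(ccl19_ids))
    vessels.ccl19_covered = [i in covered_idx for i in range(n_vessels)]

    def plant_near(vidx: int):
        """A DC center whose disk's surface gap to vessel vidx is in (0, cutoff)."""
        poly = polygons[vidx]
        ring = poly.exterior
        for _ in range(200):
            s = rng.uniform(0, ring.length)
            s = (s + rng.normal(0, config.cluster_dispersion)) % ring.length
            p = ring.interpolate(s)
            # outward normal via the nearest axis point
            ax_pt = axes[vidx].interpolate(axes[vidx].project(p))
            direction = np.array([p.x - ax_pt.x, p.y - ax_pt.y])
            norm = np.linalg.norm(direction)
            if norm == 0:
                continue
            direction /= norm
            gap = rng.uniform(0.5, cutoff - config.dc_radius - 0.5)
            center = np.array([p.x, p.y]) + direction * (gap + config.dc_radius)
            disk = Point(*center).buffer(config.dc_radius, quad_segs=16)
            d = disk.distance(poly)
            if 0 < d <= cutoff - 0.25 and _inside_field(center, config):
                return center, disk
        raise RuntimeError("failed to plant a perivascular DC; check geometry parameters")

    def plant_background():
        for _ in range(5000):
            center = rng.uniform([0, 0], [config.field_width, config.field_height])
            disk = Point(*center).buffer(config.dc_radius, quad_segs=16)
            if all(disk.distance(p) > cutoff + _GAP_MARGIN for p in polygons):
                return center, disk
        raise RuntimeError("failed to place a background cell away from all vessels; "
                           "the field is too crowded with vessels")

    n_bv_dc = int(round(config.perivascular_fraction * config.n_dc))
    n_lv_dc = int(round(config.perilymphatic_fraction * config.n_dc))
    if n_bv_dc and config.n_vessels_bv == 0:
        raise ValueError("perivascular_fraction > 0 requires at least one blood vessel")
    if n_lv_dc and config.n_vessels_lv == 0:
        raise ValueError("perilymphatic_fraction > 0 requires at least one lymphatic vessel")

    lv_idx = [i for i, c in enumerate(classes) if c == "LV"]
    records, dc_polys, dc_ids, dc_truth = [], [], [], {}
    for k in range(config.n_dc):
        cid = f"DC{k:04d}"
        if k < n_bv_dc:
            anchor = bv_idx[k % len(bv_idx)]
            center, disk = plant_near(anchor)
            label = "BV"
        elif k < n_bv_dc + n_lv_dc:
            anchor = lv_idx[(k - n_bv_dc) % len(lv_idx)]
            center, disk = plant_near(anchor)
            label = "LV"
        else:
            anchor = None
            center, disk = plant_background()
            label = "none"
        dc_ids.append(cid)
        dc_polys.append(disk)
        dc_truth[cid] = {"association": label, "anchor_vessel": None if anchor is None else vessel_ids[anchor]}
        records.append((cid, config.sample_id, center[0], center[1], "DC"))

    for k in range(config.n_treg):
        center, _ = plant_background()
        records.append((f"TR{k:04d}", config.sample_id, center[0], center[1], "Treg"))
    for k in range(config.n_other):
        center, _ = plant_background()
        records.append((f"OT{k:04d}", config.sample_id, center[0], center[1], "Other"))

    cells = pd.DataFrame(records, columns=["cell_id", "sample_id", "x_um", "y_um", "cell_type"])
    dc_surfaces = SurfaceSet(dc_ids, dc_polys, ["FSCN1"] * len(dc_ids))
    truth = {
        "dc_association": {cid: v["association"] for cid, v in dc_truth.items()},
        "dc_anchor": {cid: v["anchor_vessel"] for cid, v in dc_truth.items()},
        "vessel_class": dict(zip(vessel_ids, classes)),
        "ccl19_covered": dict(zip(vessel_ids, vessels.ccl19_covered)),
        "perivascular_fraction_planted": n_bv_dc / config.n_dc if config.n_dc else float("nan"),
        "association_cutoff": cutoff,
    }
    return Scene(cells=cells, dc_surfaces=dc_surfaces, vessels=vessels, ccl19=ccl19, truth=truth)


def _inside_field(center, cfg: SceneConfig) -> bool:
    return (0 <= center[0] <= cfg.field_width) and (0 <= center[1] <= cfg.field_height)


def _merge_episodes(episodes):
    """Merge overlapping or adjacent planted episodes of the same pair."""
    by_pair: dict = {}
    for dc, tr, s, e in episodes:
        by_pair.setdefault((dc, tr), []).append((s, e))
    merged, n_merged = [], 0
    for (dc, tr), spans in by_pair.items():
        spans.sort()
        cur_s, cur_e = spans[0]
        for s, e in spans[1:]:
            if s <= cur_e + 1:
                cur_e = max(cur_e, e)
                n_merged += 1
            else:
                merged.append((dc, tr, cur_s, cur_e))
                cur_s, cur_e = s, e
        merged.append((dc, tr, cur_s, cur_e))
    if n_merged:
        warnings.warn(f"merged {n_merged} overlapping planted episodes")
    return sorted(merged)


def generate_tracks(config: TrackConfig) -> Tuple[pd.DataFrame, list]:
    """Generate DC/Treg tracks with planted contact episodes.

    Tracks sit on a coarse spatial grid (DC homes on one row, Treg
    homes on a distant row) and perform bounded random walks, so outside
    planted episodes every DC–Treg surface distance exceeds the contact
    threshold by a wide margin by construction.  During an episode the
    Treg is carried along with its DC at a fixed small surface gap
    (``contact_gap``, default 2 μm).  Episodes of the same pair that
    overlap or touch are merged with a warning; overlapping episodes of
    the same Treg with two different DCs are rejected, since a single
    object cannot be in contact with two separated partners at once.

    Returns the track table and the merged episode list
    ``[(dc_id, treg_id, start_frame, end_frame), ...]``.
    """
    rng = np.random.default_rng(config.seed)
    episodes = _merge_episodes(config.planted_episodes)

    busy: dict = {}
    for dc, tr, s, e in episodes:
        for f in range(s, e + 1):
            key = (tr, f)
            if key in busy and busy[key] != dc:
                raise ValueError(
                    f"Treg {tr} has overlapping episodes with DCs {busy[key]} and {dc} at frame {f}"
                )
            busy[key] = dc

    pitch, row_gap, box = 150.0, 1000.0, 15.0
    n_frames = config.n_frames
    r = config.object_radius

    def walk(home, n):
        steps = rng.normal(0, config.motility_sd, size=(n, 3))
        steps[:, 2] *= 0.3  # flatter z motility, matching shallow imaging volumes
        pos = np.cumsum(steps, axis=0)
        pos = np.clip(pos, -box, box)
        return home[None, :] + pos

    dc_pos = {
        i: walk(np.array([i * pitch, 0.0, 0.0]), n_frames) for i in range(config.n_dc_tracks)
    }
    treg_pos = {
        j: walk(np.array([j * pitch, row_gap, 0.0]), n_frames)
        for j in range(config.n_treg_tracks)
    }

    # carry the Treg with its DC during planted episodes
    for dc, tr, s, e in episodes:
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        offset = u * (2 * r + config.contact_gap)
        for f in range(s, e + 1):
            treg_pos[tr][f] = dc_pos[dc][f] + offset

    rows = []
    for i in range(config.n_dc_tracks):
        for f in range(n_frames):
            x, y, z = dc_pos[i][f]
            rows.append((f"DC{i:03d}", "DC", f, f * config.frame_interval, x, y, z, r))
    for j in range(config.n_treg_tracks):
        for f in range(n_frames):
            x, y, z = treg_pos[j][f]
            rows.append((f"TR{j:03d}", "Treg", f, f * config.frame_interval, x, y, z, r))
    tracks = pd.DataFrame(
        rows, columns=["object_id", "class", "frame", "t_s", "x_um", "y_um", "z_um", "radius_um"]
    )
    named = [(f"DC{dc:03d}", f"TR{tr:03d}", s, e) for dc, tr, s, e in episodes]
    return tracks, named


def sample_episodes(
    rng: np.random.Generator,
    n_dc: int,
    n_treg: int,
    n_episodes: int,
    n_frames: int,
    max_len: int = 8,
) -> list:
    """Random non-conflicting planted episodes (no same-pair or same-Treg overlap)."""
    episodes, used = [], {}
    guard = 0
    while len(episodes) < n_episodes:
        guard += 1
        if guard > 200 * n_episodes + 1000:
            raise RuntimeError("could not place the requested number of episodes; "
                               "increase n_frames or track counts")
        dc = int(rng.integers(n_dc))
        tr = int(rng.integers(n_treg))
        start = int(rng.integers(0, n_frames - 1))
        end = min(n_frames - 1, start + int(rng.integers(1, max_len)))
        # keep one clear frame on each side so recovery is exact
        span = set(range(start - 1, end + 2))
        if used.get(tr, set()) & span:
            continue
        used.setdefault(tr, set()).update(span)
        episodes.append((dc, tr, start, end))
    return sorted(episodes)


def generate_expression(config: ExpressionConfig) -> pd.DataFrame:
    """Expression CellMap with a planted signature-positive population.

    Per-gene baseline means are drawn once (uniform on [0, 3]); cells
    get Gaussian expression around them with ``noise_sd`` dispersion.
    A ``positive_fraction`` of cells is shifted by ``effect_size`` on
    every signature gene; the planted class is stored in
    ``true_positive``.
    """
    if not config.signature_genes:
        raise ValueError("signature gene set must not be empty")
    rng = np.random.default_rng(config.seed)
    genes = [f"gene_{i:03d}" for i in range(config.n_genes)]
    sig = [g if g.startswith("gene_") else f"gene_{g}" for g in config.signature_genes]
    base = rng.uniform(0, 3, size=config.n_genes)
    X = rng.normal(base[None, :], config.noise_sd, size=(config.n_cells, config.n_genes))
    n_pos = int(round(config.positive_fraction * config.n_cells))
    pos_idx = rng.choice(config.n_cells, size=n_pos, replace=False)
    sig_cols = [genes.index(g) for g in sig]
    X[np.ix_(pos_idx, sig_cols)] += config.effect_size
    cells = pd.DataFrame(
        {
            "cell_id": [f"C{i:05d}" for i in range(config.n_cells)],
            "sample_id": "S0",
            "x_um": rng.uniform(0, 1000, config.n_cells),
            "y_um": rng.uniform(0, 1000, config.n_cells),
            "cell_type": "cell",
        }
    )
    truth = np.zeros(config.n_cells, dtype=bool)
    truth[pos_idx] = True
    cells["true_positive"] = truth
    expr = pd.DataFrame(X, columns=genes, index=cells.index)
    return pd.concat([cells, expr], axis=1)
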