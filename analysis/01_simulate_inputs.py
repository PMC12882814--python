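#!/usr/bin/env python
"""Generate the synthetic study inputs used by the downstream analyses.

Writes a tissue scene (typed cells, DC detection surfaces, classified
vessels with Ccl19 shells), a time-lapse track set with planted DC-Treg
contact episodes, and an expression matrix with a planted
signature-positive population.  Raw data files go to scratch/ (they are
regenerated on demand); a small manifest of what was planted goes to
results/.
"""

import json
from pathlib import Path

import numpy as np

from dcniche import (
    ExpressionConfig,
    SceneConfig,
    TrackConfig,
    generate_expression,
    generate_scene,
    generate_tracks,
    sample_episodes,
)
from dcniche.io import write_cells, write_surfaces, write_tracks, write_vessels

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "scratch" / "data"
RESULTS = ROOT / "results"
SEED = 20240917


def main():
    DATA.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(exist_ok=True)

    scene_cfg = SceneConfig(n_dc=300, n_treg=150, n_other=300,
                            perivascular_fraction=0.5, perilymphatic_fraction=0.2,
                            ccl19_cover_fraction=0.5, seed=SEED)
    scene = generate_scene(scene_cfg)
    write_cells(scene.cells, DATA / "cells.csv")
    write_surfaces(scene.dc_surfaces, DATA / "dc_detections.geojson")
    write_vessels(scene.vessels, DATA / "vessels.geojson")
    write_surfaces(scene.ccl19, DATA / "ccl19.geojson")
    (DATA / "scene_truth.json").write_text(json.dumps(scene.truth, indent=2, sort_keys=True))

    rng = np.random.default_rng(SEED)
    episodes = sample_episodes(rng, n_dc=10, n_treg=30, n_episodes=60, n_frames=120)
    track_cfg = TrackConfig(n_dc_tracks=10, n_treg_tracks=30, n_frames=120,
                            planted_episodes=episodes, seed=SEED)
    tracks, named = generate_tracks(track_cfg)
    write_tracks(tracks, DATA / "tracks.csv")
    (DATA / "track_truth.json").write_text(json.dumps({"episodes": named}, indent=2))

    expr_cfg = ExpressionConfig(n_cells=5000, n_genes=200, positive_fraction=0.3,
                                effect_size=3.0, noise_sd=0.5, seed=SEED)
    expr = generate_expression(expr_cfg)
    write_cells(expr, DATA / "expression.csv")

    manifest = {
        "seed": SEED,
        "scene": {"n_dc": scene_cfg.n_dc,
                  "planted_bv_fraction": scene.truth["perivascular_fraction_planted"],
                  "planted_lv_fraction": scene_cfg.perilymphatic_fraction,
                  "n_vessels": len(scene.vessels)},
        "tracks": {"n_planted_episodes": len(named),
                   "frame_interval_s": track_cfg.frame_interval},
        "expression": {"n_cells": expr_cfg.n_cells,
                       "positive_fraction": expr_cfg.positive_fraction},
    }
    (RESULTS / "simulation_manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    print("planted inputs written to", DATA)
    print(json.dumps(manifest, indent=2, sort_keys=True))


if __name__ == "__main__":
    main()
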