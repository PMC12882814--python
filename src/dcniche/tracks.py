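"""Time-lapse statistics for DC–Treg interaction dynamics.

Tracks are tables of per-frame object states (id, class, frame,
timestamp, 3-D centroid, equivalent radius).  Objects are approximated
as spheres, so the surface distance between two objects at a co-observed
frame is ``max(0, centroid distance − r_a − r_b)``.  A contact episode
is a maximal run of consecutive co-observed frames with surface distance
strictly below the threshold (5 μm); cumulative interactions use the
centroid rule (< 20 μm).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "TRACK_COLUMNS",
    "validate_tracks",
    "detect_contacts",
    "cumulative_interactions",
    "track_speed",
]

TRACK_COLUMNS = ["object_id", "class", "frame", "t_s", "x_um", "y_um", "z_um", "radius_um"]


def validate_tracks(tracks: pd.DataFrame) -> pd.DataFrame:
    """Check the track-table schema and per-object time ordering."""
    missing = [c for c in TRACK_COLUMNS if c not in tracks.columns]
    if missing:
        raise ValueError(f"track table missing columns: {missing}")
    if (tracks["radius_um"] < 0).any():
        raise ValueError("equivalent radius must be >= 0")
    for oid, grp in tracks.groupby("object_id", sort=False):
        t = grp.sort_values("frame")["t_s"].to_numpy(float)
        if np.any(np.diff(t) <= 0):
            raise ValueError(f"object {oid!r}: timestamps not strictly increasing")
    return tracks


def _object_frames(tracks: pd.DataFrame, cls: str) -> dict:
    out = {}
    for oid, grp in tracks[tracks["class"] == cls].groupby("object_id", sort=False):
        out[oid] = grp.sort_values("frame").set_index("frame")
    return out


def detect_contacts(
    tracks: pd.DataFrame,
    threshold: float = 5.0,
    gap_tolerance: int = 0,
) -> pd.DataFrame:
    """DC–Treg contact episodes and durations.

    Per DC–Treg pair, an episode is a maximal run of consecutive
    co-observed frames whose sphere surface distance is strictly below
    ``threshold``.  The run of n frames is scored as n sampling
    intervals: duration = n × (mean local frame interval), reported in
    minutes.  ``gap_tolerance`` allows up to that many missed frames
    inside an episode (0 by default: any gap breaks it).  Pairs with no
    common frames are skipped and listed in
    ``result.attrs["skipped_pairs"]``.
    """
    validate_tracks(tracks)
    dcs = _object_frames(tracks, "DC")
    tregs = _object_frames(tracks, "Treg")
    episodes, skipped = [], []
    for dc_id, dtr in dcs.items():
        for tr_id, ttr in tregs.items():
            common = dtr.index.intersection(ttr.index)
            if len(common) == 0:
                skipped.append((dc_id, tr_id))
                continue
            common = common.sort_values()
            a = dtr.loc[common, ["x_um", "y_um", "z_um"]].to_numpy(float)
            b = ttr.loc[common, ["x_um", "y_um", "z_um"]].to_numpy(float)
            gap = np.sqrt(((a - b) ** 2).sum(axis=1))
            gap -= dtr.loc[common, "radius_um"].to_numpy(float)
            gap -= ttr.loc[common, "radius_um"].to_numpy(float)
            gap = np.maximum(gap, 0.0)
            below = gap < threshold
            frames = common.to_numpy()
            times = dtr.loc[common, "t_s"].to_numpy(float)
            dt_mean = float(np.diff(times).mean()) if len(times) > 1 else float("nan")
            run_start = None
            prev_frame = None
            for i, fr in enumerate(frames):
                broken = (
                    run_start is not None
                    and prev_frame is not None
                    and fr - prev_frame > 1 + gap_tolerance
                )
                if below[i]:
                    if run_start is None or broken:
                        if run_start is not None and broken:
                            episodes.append((dc_id, tr_id, run_start, prev_frame))
                        run_start = fr
                else:
                    if run_start is not None:
                        episodes.append((dc_id, tr_id, run_start, prev_frame))
                        run_start = None
                prev_frame = fr
            if run_start is not None:
                episodes.append((dc_id, tr_id, run_start, prev_frame))
            # attach this pair's local frame interval to its new episodes
            for k, ep in enumerate(episodes):
                if len(ep) == 4:
                    episodes[k] = ep + (dt_mean,)
    rows = []
    for dc_id, tr_id, start, end, dt_mean in episodes:
        n_frames = end - start + 1
        dur_min = n_frames * dt_mean / 60.0 if dt_mean == dt_mean else float("nan")
        rows.append((dc_id, tr_id, int(start), int(end), dur_min))
    out = pd.DataFrame(
        rows, columns=["dc_id", "treg_id", "start_frame", "end_frame", "duration_min"]
    )
    out = out.sort_values(["dc_id", "treg_id", "start_frame"], kind="stable").reset_index(drop=True)
    out.attrs["skipped_pairs"] = skipped
    return out


def cumulative_interactions(tracks: pd.DataFrame, radius: float = 20.0) -> pd.DataFrame:
    """Per-DC Treg interaction counts over time (centroid rule, < ``radius``).

    Returns one row per (DC, frame) with the instantaneous number of
    Tregs strictly within ``radius`` (centroid-to-centroid) and the
    cumulative number of interaction episodes started up to that frame
    (an episode per Treg begins each time it re-enters the radius).
    Both counts are emitted; the episode curve is the headline.
    """
    validate_tracks(tracks)
    dcs = _object_frames(tracks, "DC")
    tregs = _object_frames(tracks, "Treg")
    rows = []
    for dc_id, dtr in dcs.items():
        frames = dtr.index.to_numpy()
        per_frame = np.zeros(len(frames), dtype=int)
        new_episodes = np.zeros(len(frames), dtype=int)
        for tr_id, ttr in tregs.items():
            common_mask = np.isin(frames, ttr.index)
            inside_prev = False
            for i, fr in enumerate(frames):
                if not common_mask[i]:
                    inside_prev = False
                    continue
                a = dtr.loc[fr, ["x_um", "y_um", "z_um"]].to_numpy(float)
                b = ttr.loc[fr, ["x_um", "y_um", "z_um"]].to_numpy(float)
                inside = float(np.sqrt(((a - b) ** 2).sum())) < radius
                if inside:
                    per_frame[i] += 1
                    if not inside_prev:
                        new_episodes[i] += 1
                inside_prev = inside
        cum = np.cumsum(new_episodes)
        for i, fr in enumerate(frames):
            rows.append((dc_id, int(fr), float(dtr.loc[fr, "t_s"]), int(per_frame[i]), int(cum[i])))
    return pd.DataFrame(
        rows, columns=["dc_id", "frame", "t_s", "n_tregs_within", "cumulative_episodes"]
    )


def track_speed(tracks: pd.DataFrame) -> pd.Series:
    """Mean track speed per object: total path length / total elapsed time (μm/s).

    Single-frame tracks yield NaN and a warning.
    """
    validate_tracks(tracks)
    speeds = {}
    for oid, grp in tracks.groupby("object_id", sort=False):
        grp = grp.sort_values("frame")
        xyz = grp[["x_um", "y_um", "z_um"]].to_numpy(float)
        t = grp["t_s"].to_numpy(float)
        if len(grp) < 2:
            warnings.warn(f"object {oid!r} has a single frame; speed undefined")
            speeds[oid] = float("nan")
            continue
        path = float(np.sqrt(((np.diff(xyz, axis=0)) ** 2).sum(axis=1)).sum())
        speeds[oid] = path / float(t[-1] - t[0])
    return pd.Series(speeds, name="speed_um_per_s")
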