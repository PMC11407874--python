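"""Nearest-neighbour trajectory linking between successive frames.

Follow-neighbour association: candidate pairs within a gate radius are
accepted greedily in order of ascending centroid distance, one-to-one.  The
greedy rule is deterministic (ties broken by distance, then the two frame
indices) and adequate at colony-edge densities where the per-frame motion is
small compared with the cell spacing; it is a documented swap point should a
globally optimal assignment ever be needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class LinkConfig:
    gate_radius: float = 2.0  # µm, maximum displacement per frame
    min_track_length: int = 2  # frames
    allow_gap: bool = False  # gap closing is not implemented

    def __post_init__(self) -> None:
        if self.gate_radius <= 0:
            raise ValueError("gate_radius must be positive")
        if self.min_track_length < 2:
            raise ValueError("min_track_length must be at least 2")
        if self.allow_gap:
            raise NotImplementedError("gap closing is not supported")


@dataclass
class Trajectory:
    """Time-ordered positions of one tracked cell (consecutive frames)."""

    track_id: int
    frames: np.ndarray  # (n,) int, consecutive
    xy: np.ndarray  # (n, 2) µm
    frame_interval: float  # s
    major_um: np.ndarray | None = None  # per-frame body length, if measured

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.xy = np.asarray(self.xy, dtype=float)
        if len(self.frames) != len(self.xy):
            raise ValueError("frames and xy must have equal length")
        if len(self.frames) and np.any(np.diff(self.frames) != 1):
            raise ValueError("trajectory frames must be consecutive")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def start_frame(self) -> int:
        return int(self.frames[0])

    @property
    def end_frame(self) -> int:
        return int(self.frames[-1])


def _centroids(obs) -> np.ndarray:
    """Accept an (n, 2) array or a list of objects with centroid attributes."""
    if isinstance(obs, np.ndarray):
        return obs.reshape(-1, 2)
    if len(obs) == 0:
        return np.empty((0, 2))
    first = obs[0]
    if hasattr(first, "centroid_x"):
        return np.array([[o.centroid_x, o.centroid_y] for o in obs])
    return np.asarray(obs, dtype=float).reshape(-1, 2)


def link_successive(obs_t, obs_t1, cfg: LinkConfig) -> list[tuple[int, int]]:
    """Greedy one-to-one match between two adjacent frames.

    Returns index pairs ``(i, j)`` meaning observation ``i`` of the first
    frame continues as observation ``j`` of the second.
    """
    a = _centroids(obs_t)
    b = _centroids(obs_t1)
    if len(a) == 0 or len(b) == 0:
        return []
    d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=-1)
    ii, jj = np.nonzero(d <= cfg.gate_radius)
    order = sorted(range(len(ii)), key=lambda k: (d[ii[k], jj[k]], ii[k], jj[k]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    matches: list[tuple[int, int]] = []
    for k in order:
        i, j = int(ii[k]), int(jj[k])
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        matches.append((i, j))
    return matches


def build_trajectories(
    observations: pd.DataFrame,
    cfg: LinkConfig,
    frame_interval: float,
) -> tuple[list[Trajectory], dict]:
    """Chain frame-to-frame matches into trajectories.

    ``observations`` needs columns ``frame``, ``x_um``, ``y_um`` (and
    optionally ``major_um``).  Unmatched observations open new tracks; tracks
    shorter than ``min_track_length`` are discarded.  Returns the tracks plus
    a count summary (tracks built, observations used/discarded).
    """
    if observations.empty:
        return [], {"n_tracks": 0, "n_observations": 0, "n_discarded_observations": 0}
    frames_col = observations["frame"].to_numpy()
    if not np.issubdtype(frames_col.dtype, np.integer):
        if not np.allclose(frames_col, np.round(frames_col)):
            raise ValueError("frame indices must be integers")
        frames_col = np.round(frames_col).astype(int)
    if np.any(frames_col < 0):
        raise ValueError("frame indices must be non-negative")

    has_major = "major_um" in observations.columns
    per_frame: dict[int, dict] = {}
    for f in np.unique(frames_col):
        sub = observations[frames_col == f]
        per_frame[int(f)] = {
            "xy": sub[["x_um", "y_um"]].to_numpy(dtype=float),
            "major": sub["major_um"].to_numpy(dtype=float) if has_major else None,
        }

    f_min, f_max = int(frames_col.min()), int(frames_col.max())
    open_tracks: dict[int, dict] = {}  # index within current frame -> track record
    finished: list[dict] = []

    def new_record(f: int, idx: int) -> dict:
        fr = per_frame[f]
        return {
            "frames": [f],
            "xy": [fr["xy"][idx]],
            "major": [fr["major"][idx]] if has_major else None,
        }

    cur = {i: new_record(f_min, i) for i in range(len(per_frame[f_min]["xy"]))}
    for f in range(f_min, f_max):
        nxt_data = per_frame.get(f + 1)
        cur_xy = per_frame[f]["xy"] if f in per_frame else np.empty((0, 2))
        nxt_xy = nxt_data["xy"] if nxt_data is not None else np.empty((0, 2))
        matches = link_successive(cur_xy, nxt_xy, cfg)
        matched_next = {}
        for i, j in matches:
            if i in cur:
                matched_next[j] = cur.pop(i)
        finished.extend(cur.values())  # tracks that found no continuation
        cur = {}
        for j in range(len(nxt_xy)):
            if j in matched_next:
                rec = matched_next[j]
                rec["frames"].append(f + 1)
                rec["xy"].append(nxt_xy[j])
                if has_major:
                    rec["major"].append(nxt_data["major"][j])
                cur[j] = rec
            else:
                cur[j] = new_record(f + 1, j)
    finished.extend(cur.values())

    tracks: list[Trajectory] = []
    n_used = 0
    for rec in finished:
        if len(rec["frames"]) < cfg.min_track_length:
            continue
        tracks.append(
            Trajectory(
                track_id=len(tracks),
                frames=np.array(rec["frames"]),
                xy=np.array(rec["xy"]),
                frame_interval=frame_interval,
                major_um=np.array(rec["major"]) if has_major else None,
            )
        )
        n_used += len(rec["frames"])
    counts = {
        "n_tracks": len(tracks),
        "n_observations": int(len(observations)),
        "n_discarded_observations": int(len(observations) - n_used),
    }
    return tracks, counts


def trajectories_to_dataframe(tracks: list[Trajectory]) -> pd.DataFrame:
    rows = []
    for t in tracks:
        for k in range(len(t)):
            rows.append(
                {
                    "track_id": t.track_id,
                    "frame": int(t.frames[k]),
                    "x_um": t.xy[k, 0],
                    "y_um": t.xy[k, 1],
                    "major_um": float(t.major_um[k]) if t.major_um is not None else np.nan,
                }
            )
    return pd.DataFrame(rows, columns=["track_id", "frame", "x_um", "y_um", "major_um"])


def trajectories_from_dataframe(
    df: pd.DataFrame, frame_interval: float
) -> list[Trajectory]:
    tracks = []
    has_major = "major_um" in df.columns and df["major_um"].notna().any()
    for tid, sub in df.groupby("track_id", sort=True):
        sub = sub.sort_values("frame")
        tracks.append(
            Trajectory(
                track_id=int(tid),
                frames=sub["frame"].to_numpy(dtype=int),
                xy=sub[["x_um", "y_um"]].to_numpy(dtype=float),
                frame_interval=frame_interval,
                major_um=sub["major_um"].to_numpy(dtype=float) if has_major else None,
            )
        )
    return tracks


def ground_truth_to_trajectories(tset) -> list[Trajectory]:
    """View a synthetic ground-truth set as perfect tracks (no linking)."""
    return [
        Trajectory(
            track_id=int(tset.cell_ids[c]),
            frames=np.arange(tset.n_frames),
            xy=tset.positions[c],
            frame_interval=tset.frame_interval,
        )
        for c in range(tset.n_cells)
    ]
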