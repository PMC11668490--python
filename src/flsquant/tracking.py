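"""Time-lapse linking of FLS detections and first-detection alignment.

Structures are anchored to the bilayer, so their base centroids move far
less than their tips; frame-to-frame identity is therefore assigned by
base-centroid distance.  Matching is one-to-one per frame pair: mutual
nearest neighbours are linked first, then the remaining pairs by
increasing distance, all within ``max_link_dist``.  Unmatched detections
start new tracks and a missed frame terminates a track — there is no gap
closing, consistent with requiring a minimum number of *consecutive*
frames for inclusion (six frames = 2 min at 20 s intervals).

The aligned profile sets T = 0 at each track's first detection and
reports the mean (± SEM) length over all tracks still present at each
relative time point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .segmentation import FLSPath

__all__ = [
    "Track",
    "TrackSet",
    "AlignedLengthProfile",
    "track_fls",
    "filter_tracks",
    "aligned_length_profile",
]


@dataclass
class Track:
    track_id: int
    start_frame: int
    paths: list[FLSPath] = field(default_factory=list)

    @property
    def n_frames(self) -> int:
        return len(self.paths)

    @property
    def frames(self) -> list[int]:
        return list(range(self.start_frame, self.start_frame + len(self.paths)))

    @property
    def lengths(self) -> np.ndarray:
        return np.array([p.path_length for p in self.paths])

    @property
    def last_base(self) -> tuple[float, float]:
        return self.paths[-1].base_centroid


@dataclass
class TrackSet:
    tracks: list[Track]
    frame_interval: float = 20.0  # s

    def __len__(self) -> int:
        return len(self.tracks)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.tracks:
            for k, (f, length) in enumerate(zip(t.frames, t.lengths)):
                rows.append(
                    {
                        "track_id": t.track_id,
                        "frame": f,
                        "rel_time_s": k * self.frame_interval,
                        "length_um": length,
                        "base_x_um": t.paths[k].base_centroid[0],
                        "base_y_um": t.paths[k].base_centroid[1],
                    }
                )
        return pd.DataFrame(rows)


def _match_frame(
    prev_pts: np.ndarray, cur_pts: np.ndarray, max_link_dist: float
) -> list[tuple[int, int]]:
    """One-to-one matches (prev_idx, cur_idx): mutual NN first, then greedy."""
    if len(prev_pts) == 0 or len(cur_pts) == 0:
        return []
    dist = cdist(prev_pts, cur_pts)
    matches: list[tuple[int, int]] = []
    used_p: set[int] = set()
    used_c: set[int] = set()
    nn_of_prev = np.argmin(dist, axis=1)
    nn_of_cur = np.argmin(dist, axis=0)
    for i, j in enumerate(nn_of_prev):
        if nn_of_cur[j] == i and dist[i, j] <= max_link_dist:
            matches.append((i, int(j)))
            used_p.add(i)
            used_c.add(int(j))
    order = np.dstack(np.unravel_index(np.argsort(dist, axis=None), dist.shape))[0]
    for i, j in order:
        if dist[i, j] > max_link_dist:
            break
        if i in used_p or j in used_c:
            continue
        matches.append((int(i), int(j)))
        used_p.add(int(i))
        used_c.add(int(j))
    return matches


def track_fls(
    frames: list[list[FLSPath]],
    max_link_dist: float = 1.0,
    frame_interval: float = 20.0,
) -> TrackSet:
    """Link per-frame detections into tracks by base-centroid proximity."""
    if max_link_dist <= 0:
        raise ValueError("max_link_dist must be positive")
    tracks: list[Track] = []
    active: list[Track] = []
    for f, detections in enumerate(frames):
        matches = _match_frame(
            np.array([t.last_base for t in active]).reshape(-1, 2),
            np.array([p.base_centroid for p in detections]).reshape(-1, 2),
            max_link_dist,
        )
        matched_prev = {i for i, _ in matches}
        matched_cur = {j for _, j in matches}
        for i, j in matches:
            active[i].paths.append(detections[j])
        survivors = [t for i, t in enumerate(active) if i in matched_prev]
        for j, det in enumerate(detections):
            if j not in matched_cur:
                t = Track(track_id=len(tracks), start_frame=f, paths=[det])
                tracks.append(t)
                survivors.append(t)
        active = survivors
    # tracks list already contains every started track (paths grew in place)
    for t in tracks:
        if not t.paths:
            raise AssertionError("empty track")  # pragma: no cover
    return TrackSet(tracks=tracks, frame_interval=frame_interval)


def filter_tracks(track_set: TrackSet, min_track_frames: int = 6) -> TrackSet:
    """Drop tracks detected for fewer than ``min_track_frames`` consecutive frames."""
    kept = [t for t in track_set.tracks if t.n_frames >= min_track_frames]
    return TrackSet(tracks=kept, frame_interval=track_set.frame_interval)


@dataclass
class AlignedLengthProfile:
    """Mean length vs time since first detection, across tracks."""

    rel_time_s: np.ndarray
    mean_um: np.ndarray
    sem_um: np.ndarray
    n: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rel_time_s": self.rel_time_s,
                "mean_um": self.mean_um,
                "sem_um": self.sem_um,
                "n": self.n,
            }
        )

    def slope_um_per_min(self) -> float:
        """Least-squares slope of mean length vs time, in µm/min."""
        t_min = self.rel_time_s / 60.0
        return float(np.polyfit(t_min, self.mean_um, 1)[0])


def aligned_length_profile(track_set: TrackSet) -> AlignedLengthProfile:
    """Mean ± SEM of track lengths at each time point after first detection.

    At relative time point k, every track with at least k+1 frames
    contributes its k-th length.  SEM is reported as 0 where only one
    track contributes (n is recorded alongside).
    """
    if not track_set.tracks:
        raise ValueError("no tracks")
    horizon = max(t.n_frames for t in track_set.tracks)
    mean = np.empty(horizon)
    sem = np.empty(horizon)
    n = np.empty(horizon, dtype=int)
    for k in range(horizon):
        vals = np.array(
            [t.lengths[k] for t in track_set.tracks if t.n_frames > k]
        )
        n[k] = len(vals)
        mean[k] = vals.mean()
        sem[k] = vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else 0.0
    return AlignedLengthProfile(
        rel_time_s=np.arange(horizon) * track_set.frame_interval,
        mean_um=mean,
        sem_um=sem,
        n=n,
    )
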