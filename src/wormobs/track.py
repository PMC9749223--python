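"""Detection linking and per-track kinematics.

Tracks are gap-free by construction: detections are linked frame-to-frame by
greedy mutual nearest neighbor under a distance gate, a track ends on any
missed frame, and only tracks of at least 20 frames (10 s at 2 fps) survive
the analysis filter.  Kinematics (speed in mm/s, angular velocity in deg/s)
are computed per track over 10-s bins on the experiment's hours-after-
transfer (h.a.t.) time axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .segment import Detection

#: displacement magnitude (px) below which a frame step carries no usable
#: heading information
HEADING_NOISE_FLOOR_PX = 0.5

#: analysis discards everything earlier than this (worm-handling artifacts)
SETTLING_PERIOD_H = 0.5


@dataclass
class Track:
    """Gap-free ordered detections of one worm (or one pass of one worm)."""

    track_id: int
    detections: list = field(default_factory=list, repr=False)
    video_index: int = 0

    @property
    def start_frame(self) -> int:
        return self.detections[0].frame_index

    @property
    def end_frame(self) -> int:
        return self.detections[-1].frame_index

    def __len__(self) -> int:
        return len(self.detections)

    @property
    def centroids(self) -> np.ndarray:
        return np.array([d.centroid for d in self.detections], dtype=float)

    @property
    def net_displacement(self) -> float:
        c = self.centroids
        return float(np.linalg.norm(c[-1] - c[0]))


@dataclass
class KinematicsBin:
    """Speed / angular velocity of one track over one 10-s window."""

    track_id: int
    bin_index: int
    speed: float              # mm / s
    angular_velocity: float   # deg / s
    hat: float                # hours after transfer (bin start)
    n_frames: int
    heading_defined: bool = True


def _greedy_mutual_nn(prev_pts: np.ndarray, cur_pts: np.ndarray,
                      prev_areas: np.ndarray, cur_areas: np.ndarray,
                      max_dist: float) -> list[tuple[int, int]]:
    """Mutually-nearest pairs under the gate, greedily by distance then by
    area difference (tie-break)."""
    if len(prev_pts) == 0 or len(cur_pts) == 0:
        return []
    d = np.linalg.norm(prev_pts[:, None, :] - cur_pts[None, :, :], axis=2)
    cand = []
    for i in range(len(prev_pts)):
        j = int(np.argmin(d[i]))
        if d[i, j] <= max_dist and int(np.argmin(d[:, j])) == i:
            cand.append((d[i, j], abs(prev_areas[i] - cur_areas[j]), i, j))
    cand.sort()
    used_i, used_j, pairs = set(), set(), []
    for _, _, i, j in cand:
        if i in used_i or j in used_j:
            continue
        used_i.add(i)
        used_j.add(j)
        pairs.append((i, j))
    return pairs


def link_tracks(detections_per_frame: list[list[Detection]],
                max_link_distance: float, video_index: int = 0) -> list[Track]:
    """Link per-frame detections into gap-free tracks.

    Greedy mutual-nearest-neighbor association between consecutive frames;
    unmatched detections open new tracks; a track closes the first frame it
    goes unmatched (no gap closing).
    """
    tracks: list[Track] = []
    open_tracks: dict[int, Track] = {}   # index into previous frame's dets -> Track
    next_id = 0
    prev_dets: list[Detection] = []

    for dets in detections_per_frame:
        new_open: dict[int, Track] = {}
        if prev_dets and dets:
            pairs = _greedy_mutual_nn(
                np.array([d.centroid for d in prev_dets]),
                np.array([d.centroid for d in dets]),
                np.array([d.area for d in prev_dets]),
                np.array([d.area for d in dets]),
                max_link_distance,
            )
        else:
            pairs = []
        matched_j = set()
        for i, j in pairs:
            if i in open_tracks:
                tr = open_tracks.pop(i)
                tr.detections.append(dets[j])
                new_open[j] = tr
                matched_j.add(j)
        # unmatched current detections start new tracks
        for j, det in enumerate(dets):
            if j not in matched_j:
                tr = Track(track_id=next_id, detections=[det], video_index=video_index)
                next_id += 1
                new_open[j] = tr
        # tracks whose detection went unmatched are closed
        tracks.extend(open_tracks.values())
        open_tracks = new_open
        prev_dets = dets

    tracks.extend(open_tracks.values())
    tracks.sort(key=lambda t: t.track_id)
    return tracks


def filter_tracks(tracks: list[Track], min_frames: int = 20,
                  moving_only: bool = False,
                  worm_length: float = 48.0) -> list[Track]:
    """Drop short tracks and, optionally, non-moving ones.

    Non-moving tracks (net displacement < half a body length) are usually
    segmentation artifacts — stains or debris detected frame after frame.
    """
    out = []
    for tr in tracks:
        if len(tr) < min_frames:
            continue
        if moving_only and tr.net_displacement < 0.5 * worm_length:
            continue
        out.append(tr)
    return out


def _bin_kinematics(centroids: np.ndarray, pixel_size: float,
                    frame_rate: float,
                    heading_smooth_window: int = 3) -> tuple[float, float, bool]:
    """(speed mm/s, angular velocity deg/s, heading_defined) of one window."""
    steps = np.diff(centroids, axis=0)
    step_len = np.linalg.norm(steps, axis=1)
    duration_s = len(steps) / frame_rate
    speed = step_len.sum() * pixel_size / 1000.0 / duration_s  # um -> mm

    # headings from a lightly smoothed path: centroid localization noise
    # otherwise dominates the frame-to-frame heading change
    from .geometry import smooth_path
    s_steps = np.diff(smooth_path(centroids, heading_smooth_window), axis=0)
    if len(s_steps) >= 4:
        s_steps = s_steps[1:-1]  # boundary steps are only partially smoothed
    s_len = np.linalg.norm(s_steps, axis=1)
    moving = s_len >= HEADING_NOISE_FLOOR_PX
    headings = np.arctan2(s_steps[moving, 1], s_steps[moving, 0])
    if len(headings) < 2:
        return speed, 0.0, False
    dh = np.arctan2(np.sin(np.diff(headings)), np.cos(np.diff(headings)))
    ang_vel = float(np.degrees(np.mean(np.abs(dh))) * frame_rate)
    return speed, ang_vel, True


def compute_kinematics(track: Track, pixel_size: float, frame_rate: float,
                       bin_seconds: float = 10.0,
                       start_time_s: float = 0.0) -> list[KinematicsBin]:
    """Per-10-s-bin speed and angular velocity of one track.

    Speed is the within-bin path length over the bin duration (mm/s).
    Angular velocity is the mean absolute change in heading between
    successive displacement vectors, scaled to deg/s; steps below the
    0.5-px noise floor carry no heading.  Bins with fewer than 2 frames
    are not emitted; an all-stationary bin reports angular velocity 0
    with ``heading_defined=False``.
    """
    frames_per_bin = int(round(bin_seconds * frame_rate))
    cents = track.centroids
    bins = []
    for b in range(len(cents) // frames_per_bin):
        chunk = cents[b * frames_per_bin:(b + 1) * frames_per_bin]
        if len(chunk) < 2:
            continue
        speed, ang_vel, defined = _bin_kinematics(chunk, pixel_size, frame_rate)
        t0 = start_time_s + (track.start_frame + b * frames_per_bin) / frame_rate
        bins.append(KinematicsBin(
            track_id=track.track_id, bin_index=b, speed=speed,
            angular_velocity=ang_vel, hat=t0 / 3600.0,
            n_frames=len(chunk), heading_defined=defined,
        ))
    return bins


def discard_settling_period(bins: list[KinematicsBin],
                            first_hours: float = SETTLING_PERIOD_H) -> list[KinematicsBin]:
    """Drop bins from the settling period right after worm transfer
    (h.a.t. < 0.5 h by default; the boundary bin itself is kept)."""
    return [b for b in bins if b.hat >= first_hours]


def hat_hours(video_index: int, in_video_time_s: float,
              video_length_s: float = 480.0) -> float:
    """Hours-after-transfer of a time point inside a numbered video
    (videos are consecutive 8-min recordings)."""
    return (video_index * video_length_s + in_video_time_s) / 3600.0


def decimate_frames(timestamps: np.ndarray, target_fps: float) -> np.ndarray:
    """Indices that downsample a stack to ``target_fps`` by keeping, for each
    target tick, the frame with the nearest timestamp (e.g. 5 -> 2 fps)."""
    ts = np.asarray(timestamps, dtype=float)
    if len(ts) == 0:
        return np.array([], dtype=int)
    ticks = np.arange(ts[0], ts[-1] + 0.5 / target_fps, 1.0 / target_fps)
    idx = np.unique([int(np.argmin(np.abs(ts - t))) for t in ticks])
    return idx
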