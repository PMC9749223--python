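"""Worm midlines: thinning, validation, head assignment, posture angles.

A detection bitmask is thinned to a 1-px medial curve, short spurs are
pruned, and the curve is accepted only if it is unambiguous — exactly two
endpoints, no junction pixels — and at least 26 px of arc length.  Turning
(self-occluded) worms fail these criteria by design and are handled by the
shape-based turn classifier instead.

The head is the endpoint facing the direction of motion (worms crawl
head-first); ambiguous frames inherit orientation from the nearest oriented
frame of the same track, and frames that cannot be resolved either way are
discarded.  Oriented midlines are resampled to 26 equally spaced points
yielding the 24-angle posture vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.signal import savgol_filter
from skimage.morphology import skeletonize as _thin

from . import geometry

MIN_SKELETON_LENGTH_PX = 26.0
PRUNE_LENGTH_PX = 3

_NEIGH8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass
class SkeletonValidation:
    valid: bool
    reason: str | None = None          # "too_short" | "branched" | "no_endpoints" | "empty"
    path: np.ndarray | None = None     # ordered (n, 2) pixel path, (x, y)
    arc_length: float = 0.0


@dataclass
class OrientedSkeleton:
    """Head-to-tail ordered midline of one worm in one frame."""

    track_id: int
    frame_index: int
    path: np.ndarray                   # ordered (n, 2), path[0] = head, (x, y)
    arc_length: float
    head_assignment_source: str        # "motion" | "adjacent_frame"

    def posture(self) -> np.ndarray:
        return posture_angles(self)


def skeletonize_mask(mask: np.ndarray, prune_length: int = PRUNE_LENGTH_PX) -> np.ndarray:
    """Thin a connected bitmask to a 1-px skeleton and prune short spurs.

    Returns a boolean image of the same shape.  Raises on an empty mask.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("cannot skeletonize an empty mask")
    skel = _thin(mask)
    pixels = set(zip(*np.nonzero(skel)))
    pixels = _prune_spurs(pixels, prune_length)
    out = np.zeros_like(mask)
    if pixels:
        rr, cc = zip(*pixels)
        out[list(rr), list(cc)] = True
    return out


def _neighbors(p, pixels):
    r, c = p
    return [(r + dr, c + dc) for dr, dc in _NEIGH8 if (r + dr, c + dc) in pixels]


def _prune_spurs(pixels: set, prune_length: int) -> set:
    """Remove endpoint branches of <= prune_length pixels that terminate at a
    junction; repeats until stable.  Leaves junction pixels in place."""
    if prune_length <= 0:
        return pixels
    changed = True
    while changed and pixels:
        changed = False
        deg = {p: len(_neighbors(p, pixels)) for p in pixels}
        if not any(d >= 3 for d in deg.values()):
            break
        endpoints = [p for p, d in deg.items() if d == 1]
        for ep in endpoints:
            if ep not in pixels:
                continue
            branch = [ep]
            prev, cur = None, ep
            hit_junction = False
            while len(branch) <= prune_length:
                nbrs = [q for q in _neighbors(cur, pixels) if q != prev]
                if not nbrs:
                    break
                nxt = nbrs[0]
                if len(_neighbors(nxt, pixels)) >= 3:
                    hit_junction = True
                    break
                branch.append(nxt)
                prev, cur = cur, nxt
            if hit_junction and len(branch) <= prune_length:
                pixels -= set(branch)
                changed = True
    return pixels


def _order_path(pixels: set, start) -> list:
    """Walk a simple 1-px path from an endpoint, preferring 4-connected steps
    to resolve staircase ambiguity."""
    path = [start]
    visited = {start}
    cur = start
    while True:
        nbrs = [q for q in _neighbors(cur, pixels) if q not in visited]
        if not nbrs:
            break
        nbrs.sort(key=lambda q: (abs(q[0] - cur[0]) + abs(q[1] - cur[1])))
        cur = nbrs[0]
        path.append(cur)
        visited.add(cur)
    return path


def validate_skeleton(skel: np.ndarray,
                      min_length: float = MIN_SKELETON_LENGTH_PX) -> SkeletonValidation:
    """Accept only unambiguous skeletons: two endpoints, no junctions,
    arc length >= 26 px.  Returns the ordered pixel path on success."""
    skel = np.asarray(skel, dtype=bool)
    pixels = set(zip(*np.nonzero(skel)))
    if not pixels:
        return SkeletonValidation(False, "empty")
    deg = {p: len(_neighbors(p, pixels)) for p in pixels}
    if any(d >= 3 for d in deg.values()):
        return SkeletonValidation(False, "branched")
    endpoints = [p for p, d in deg.items() if d == 1]
    if len(endpoints) != 2:
        # 0 endpoints = closed loop; 1 = degenerate
        return SkeletonValidation(False, "no_endpoints" if not endpoints else "branched")
    path_rc = _order_path(pixels, endpoints[0])
    if len(path_rc) != len(pixels):
        return SkeletonValidation(False, "branched")  # disconnected remainder
    path = np.array([(c, r) for r, c in path_rc], dtype=float)  # (x, y)
    length = geometry.arc_length(path)
    if length < min_length:
        return SkeletonValidation(False, "too_short", path=path, arc_length=length)
    return SkeletonValidation(True, path=path, arc_length=length)


def orient_by_motion(path: np.ndarray, displacement: np.ndarray,
                     arc_len: float,
                     min_displacement: float = 1.0,
                     margin_fraction: float = 0.25) -> np.ndarray | None:
    """Orient a midline so the head leads, from the direction of movement.

    The head is the endpoint with the larger projection onto the (smoothed)
    displacement vector.  Accepted only when the worm moved at least
    ``min_displacement`` px/frame and the two endpoint projections differ by
    at least ``margin_fraction`` of the body length; otherwise ``None``
    (caller falls back to adjacent-frame propagation).
    """
    disp = np.asarray(displacement, dtype=float)
    norm = np.linalg.norm(disp)
    if norm < min_displacement:
        return None
    u = disp / norm
    center = path.mean(axis=0)
    proj0 = float((path[0] - center) @ u)
    proj1 = float((path[-1] - center) @ u)
    if abs(proj0 - proj1) < margin_fraction * arc_len:
        return None
    return path if proj0 > proj1 else path[::-1]


def _inherit_orientation(path: np.ndarray, oriented_neighbor: np.ndarray) -> np.ndarray:
    """Orient ``path`` so its head end is the endpoint closest to the
    neighbor frame's head."""
    head_ref = oriented_neighbor[0]
    d0 = np.linalg.norm(path[0] - head_ref)
    d1 = np.linalg.norm(path[-1] - head_ref)
    return path if d0 <= d1 else path[::-1]


def orient_track_skeletons(validations: dict, centroids: np.ndarray,
                           track_id: int = 0,
                           smooth_window: int = 3,
                           min_displacement: float = 1.0,
                           margin_fraction: float = 0.25) -> list[OrientedSkeleton]:
    """Assign heads across a whole track.

    ``validations`` maps frame offset (0-based within the track) to a valid
    :class:`SkeletonValidation`.  First pass: orientation from the smoothed
    per-frame displacement.  Second pass: unresolved frames inherit from the
    nearest motion-oriented frame (endpoint correspondence by proximity).
    Frames that remain unresolved are discarded.
    """
    n = len(centroids)
    disp = np.zeros_like(centroids)
    if n >= 2:
        disp[1:] = np.diff(centroids, axis=0)
        disp[0] = disp[1]
        disp = geometry.smooth_path(disp, window=smooth_window)

    oriented: dict[int, tuple[np.ndarray, str]] = {}
    for f, val in validations.items():
        if not val.valid:
            continue
        p = orient_by_motion(val.path, disp[f], val.arc_length,
                             min_displacement, margin_fraction)
        if p is not None:
            oriented[f] = (p, "motion")

    motion_frames = sorted(f for f, (_, src) in oriented.items() if src == "motion")
    if motion_frames:
        for f, val in validations.items():
            if not val.valid or f in oriented:
                continue
            nearest = min(motion_frames, key=lambda g: abs(g - f))
            ref, _ = oriented[nearest]
            oriented[f] = (_inherit_orientation(val.path, ref), "adjacent_frame")

    return [
        OrientedSkeleton(track_id=track_id, frame_index=f, path=p,
                         arc_length=validations[f].arc_length,
                         head_assignment_source=src)
        for f, (p, src) in sorted(oriented.items())
    ]


def refine_midline(points: np.ndarray, signal: np.ndarray,
                   half_width: float = 3.5, n_samples: int = 13,
                   n_iter: int = 3) -> np.ndarray:
    """Subpixel midline refinement against the intensity image.

    Each midline point slides along its local normal to the intensity-
    weighted center of the worm-positive signal (background minus frame),
    then the path is re-equalized in arc length; a few iterations converge.
    Recovers the sub-pixel midline position that binarization + thinning
    quantize away.
    """
    pts = np.asarray(points, dtype=float).copy()
    signal = np.asarray(signal, dtype=float)
    offs = np.linspace(-half_width, half_width, n_samples)
    for _ in range(n_iter):
        tang = np.gradient(pts, axis=0)
        norms = np.linalg.norm(tang, axis=1, keepdims=True)
        tang = tang / np.where(norms > 0, norms, 1.0)
        normal = np.stack([-tang[:, 1], tang[:, 0]], axis=1)
        coords = pts[:, None, :] + offs[None, :, None] * normal[:, None, :]
        vals = ndimage.map_coordinates(
            signal, [coords[..., 1].ravel(), coords[..., 0].ravel()],
            order=1, mode="nearest",
        ).reshape(len(pts), n_samples)
        w = np.clip(vals, 0, None)
        w = w - w.min(axis=1, keepdims=True)
        shift = (w * offs[None, :]).sum(axis=1) / np.maximum(w.sum(axis=1), 1e-9)
        pts = pts + shift[:, None] * normal
        pts = geometry.resample_midline(pts, len(pts))
    return pts


def posture_angles(skeleton: OrientedSkeleton | np.ndarray,
                   smooth_window: int = 3,
                   intensity: np.ndarray | None = None,
                   angle_filter_window: int = 9) -> np.ndarray:
    """24 signed intersegment angles of an oriented midline.

    The pixel path is lightly smoothed (moving average) to suppress
    staircase jaggies, resampled to 26 points equally spaced in arc length,
    and the signed angle between consecutive chords is taken at each of the
    24 interior joints.  Mirroring the worm flips every sign.

    When the worm-positive ``intensity`` image is supplied the resampled
    midline is refined to subpixel precision first (:func:`refine_midline`);
    ``angle_filter_window`` applies a quadratic Savitzky-Golay filter along
    the body (postures are smooth at the joint scale, pixel noise is not);
    set it to 0 to disable.
    """
    path = skeleton.path if isinstance(skeleton, OrientedSkeleton) else np.asarray(skeleton, float)
    smoothed = geometry.smooth_path(path, window=smooth_window)
    pts = geometry.resample_midline(smoothed)
    if intensity is not None:
        pts = refine_midline(pts, intensity)
    angles = geometry.angles_from_midline(pts)
    if angle_filter_window and angle_filter_window > 2:
        angles = savgol_filter(angles, angle_filter_window, 2, mode="interp")
    return angles
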