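"""Midline geometry: arc-length resampling and intersegment angles.

A worm posture is the shape of its midline, summarized as the signed planar
angles between consecutive chords of the midline resampled to 26 equally
spaced points (head to tail).  26 points give 25 chords and hence 24
intersegment angles; this 24-vector is the posture representation used by
all downstream clustering and eigen-analysis.
"""

from __future__ import annotations

import numpy as np

#: number of resampled midline points (head -> tail)
N_MIDLINE_POINTS = 26
#: number of intersegment angles (N_MIDLINE_POINTS - 2)
N_ANGLES = N_MIDLINE_POINTS - 2


def arc_length(points: np.ndarray) -> float:
    """Total polyline length of an ordered (n, 2) point path."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        return 0.0
    return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))


def smooth_path(points: np.ndarray, window: int = 3) -> np.ndarray:
    """Moving-average smoothing of an ordered path; endpoints kept fixed.

    Suppresses single-pixel jaggies of thinned skeletons before resampling.
    """
    pts = np.asarray(points, dtype=float)
    if window <= 1 or pts.shape[0] <= window:
        return pts
    kernel = np.ones(window) / window
    out = pts.copy()
    for d in range(pts.shape[1]):
        out[:, d] = np.convolve(pts[:, d], kernel, mode="same")
    # convolution shrinks the ends toward zero-padding; restore them
    half = window // 2
    out[:half] = pts[:half]
    out[-half:] = pts[-half:]
    return out


def resample_midline(points: np.ndarray, n: int = N_MIDLINE_POINTS) -> np.ndarray:
    """Resample an ordered path to ``n`` points equally spaced in arc length.

    Linear interpolation along the cumulative arc-length parameterization.
    Raises ``ValueError`` on degenerate (zero-length) input.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("midline needs at least 2 points")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] <= 0:
        raise ValueError("degenerate midline with zero arc length")
    target = np.linspace(0.0, s[-1], n)
    out = np.empty((n, 2), dtype=float)
    for d in range(2):
        out[:, d] = np.interp(target, s, pts[:, d])
    return out


def angles_from_midline(points: np.ndarray) -> np.ndarray:
    """Signed intersegment angles of an ordered midline.

    For ``m`` points there are ``m - 1`` chords and ``m - 2`` angles; the
    angle at joint ``i`` is the signed rotation (positive = counter-clockwise
    in image coordinates) from chord ``i`` to chord ``i + 1``:

        theta_i = atan2(cross(c_i, c_{i+1}), dot(c_i, c_{i+1}))

    A left-right mirrored midline yields exactly ``-theta``.
    """
    pts = np.asarray(points, dtype=float)
    chords = np.diff(pts, axis=0)
    norms = np.linalg.norm(chords, axis=1)
    if np.any(norms == 0):
        raise ValueError("degenerate (zero-length) chord in midline")
    a, b = chords[:-1], chords[1:]
    cross = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
    dot = np.sum(a * b, axis=1)
    return np.arctan2(cross, dot)


def posture_vector(points: np.ndarray, n: int = N_MIDLINE_POINTS) -> np.ndarray:
    """Resample a midline to ``n`` equally spaced points and return the
    ``n - 2`` intersegment angles (the posture vector)."""
    return angles_from_midline(resample_midline(points, n=n))


def midline_from_angles(
    angles: np.ndarray,
    segment_length: float,
    head: tuple[float, float] = (0.0, 0.0),
    heading: float = 0.0,
) -> np.ndarray:
    """Reconstruct a midline (head -> tail) from intersegment angles.

    Inverse of :func:`angles_from_midline` for equal chord lengths: the first
    chord points along ``heading`` (radians) and each subsequent chord is
    rotated by the corresponding angle.  Returns ``len(angles) + 2`` points.
    """
    ang = np.asarray(angles, dtype=float)
    psi = heading + np.concatenate([[0.0], np.cumsum(ang)])
    steps = segment_length * np.stack([np.cos(psi), np.sin(psi)], axis=1)
    pts = np.empty((len(ang) + 2, 2), dtype=float)
    pts[0] = head
    pts[1:] = np.asarray(head, dtype=float) + np.cumsum(steps, axis=0)
    return pts


def wrap_angle(a: np.ndarray | float) -> np.ndarray | float:
    """Wrap angle(s) to (-pi, pi]."""
    return np.arctan2(np.sin(a), np.cos(a))
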