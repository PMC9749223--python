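"""Per-frame worm detection: background subtraction, filtering, size selection.

The background is a per-pixel temporal median over a stride-sampled frame
window (moving worms are sparse in time, so the median suppresses them).
Detection thresholds the smoothed absolute difference at a robust
(MAD-scaled) multiple of the noise level, labels connected components, and
keeps those within a size window.  The absolute difference makes detection
sign-agnostic (dark-on-bright and bright-on-dark both work) and invariant
to a constant intensity offset applied to frame and background alike.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure

from .simulate import FrameStack


@dataclass
class SegmentParams:
    threshold_sd: float = 5.0       # threshold = threshold_sd x robust noise sd
    smoothing_sigma: float = 1.0    # Gaussian pre-smoothing, px
    min_area: float = 60.0          # px^2; ~0.5 x worm_length x worm_width
    max_area: float = 720.0         # px^2; ~3 x single-worm area

    @classmethod
    def from_worm_geometry(cls, worm_length: float, worm_width: float, **kw) -> "SegmentParams":
        area = worm_length * worm_width
        return cls(min_area=0.5 * area, max_area=3.0 * area, **kw)


@dataclass
class Detection:
    """One segmented connected component in one frame."""

    frame_index: int
    centroid: tuple            # (x, y) px
    area: float                # px^2
    mask: np.ndarray = field(repr=False)   # local boolean crop
    bbox: tuple = ()           # (min_row, min_col, max_row, max_col)
    mean_intensity: float = float("nan")

    def full_mask(self, shape: tuple) -> np.ndarray:
        """Paste the local mask back into a full-frame boolean image."""
        out = np.zeros(shape, dtype=bool)
        r0, c0, r1, c1 = self.bbox
        out[r0:r1, c0:c1] = self.mask
        return out


def estimate_background(frames, sample_stride: int = 1) -> np.ndarray:
    """Per-pixel temporal median over stride-sampled frames.

    Requires at least 3 sampled frames; a worm occupying a pixel in fewer
    than half of the sampled frames does not shift that pixel's median.
    """
    if isinstance(frames, FrameStack):
        frames = frames.frames
    frames = np.asarray(frames)
    sampled = frames[::sample_stride]
    if sampled.shape[0] < 3:
        raise ValueError(
            f"need >= 3 sampled frames to estimate background, got {sampled.shape[0]}"
        )
    return np.median(sampled.astype(float), axis=0)


def robust_noise_sd(diff: np.ndarray) -> float:
    """MAD-based noise scale of a difference image (worm pixels are sparse,
    so the median absolute deviation tracks the background noise)."""
    med = np.median(diff)
    mad = np.median(np.abs(diff - med))
    return 1.4826 * float(mad)


def segment_frame(frame: np.ndarray, background: np.ndarray,
                  params: SegmentParams | None = None,
                  frame_index: int = 0) -> list[Detection]:
    """Detect worm-shaped objects in one frame.

    |frame - background| is Gaussian-smoothed, thresholded at
    ``threshold_sd`` times the robust noise estimate, hole-filled, and
    labeled; components outside ``[min_area, max_area]`` are discarded.
    """
    params = params or SegmentParams()
    frame = np.asarray(frame, dtype=float)
    background = np.asarray(background, dtype=float)
    if frame.shape != background.shape:
        raise ValueError("frame and background dimensions differ")

    diff = frame - background
    if params.smoothing_sigma > 0:
        # smooth the signed difference so zero-mean noise cancels
        diff = ndimage.gaussian_filter(diff, params.smoothing_sigma)
    diff = np.abs(diff)
    sigma = robust_noise_sd(diff)
    if sigma == 0 and not np.any(diff > 0):
        return []
    binary = diff > params.threshold_sd * max(sigma, 1e-12)
    binary = ndimage.binary_fill_holes(binary)

    labels = measure.label(binary, connectivity=2)
    detections = []
    # weight centroids by the difference magnitude: boundary pixels flicker
    # with the noise, so the intensity-weighted centroid localizes the worm
    # to sub-pixel precision
    for region in measure.regionprops(labels, intensity_image=diff):
        if not (params.min_area <= region.area <= params.max_area):
            continue
        r0, c0, r1, c1 = region.bbox
        cy, cx = region.centroid_weighted
        detections.append(Detection(
            frame_index=frame_index,
            centroid=(cx, cy),
            area=float(region.area),
            mask=region.image.copy(),
            bbox=(r0, c0, r1, c1),
            mean_intensity=float(region.intensity_mean),
        ))
    return detections


def segment_stack(stack: FrameStack, params: SegmentParams | None = None,
                  background: np.ndarray | None = None,
                  sample_stride: int = 1) -> list[list[Detection]]:
    """Segment every frame of a stack against a shared background."""
    if background is None:
        background = estimate_background(stack, sample_stride=sample_stride)
    return [
        segment_frame(stack.frames[i], background, params, frame_index=i)
        for i in range(len(stack))
    ]
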