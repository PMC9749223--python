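"""Shared fixtures: one small simulated plate scene reused across modules."""

import numpy as np
import pytest

from wormobs import segment, track
from wormobs.simulate import SimConfig, simulate_plate


@pytest.fixture(scope="session")
def scene():
    """A 512-px plate scene: 5 worms, 60 s at 2 fps, all behavioral states."""
    cfg = SimConfig(image_size=512, n_worms=5, duration=60.0, rng_seed=2)
    stack, gt = simulate_plate(cfg)
    return cfg, stack, gt


@pytest.fixture(scope="session")
def scene_detections(scene):
    cfg, stack, _ = scene
    params = segment.SegmentParams.from_worm_geometry(cfg.worm_length, cfg.worm_width)
    return segment.segment_stack(stack, params)


@pytest.fixture(scope="session")
def scene_tracks(scene, scene_detections):
    cfg, _, _ = scene
    tracks = track.link_tracks(scene_detections, max_link_distance=cfg.worm_length)
    return track.filter_tracks(tracks, min_frames=20)


def match_worm(gt, frame_index, centroid):
    """Index of the ground-truth worm nearest a detection centroid."""
    d = np.linalg.norm(gt.centroids[frame_index] - np.asarray(centroid), axis=1)
    return int(np.argmin(d))
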