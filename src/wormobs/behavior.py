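"""Behavioral-state quantification from kinematics and shape.

Dispersal — fast, straight locomotion — is defined on 10-s kinematics bins
by two thresholds: speed >= 0.01 mm/s AND angular velocity < 15 deg/s.
Quiescence is reported descriptively as speed below the dispersal floor.
Turns (omega / U shapes) defeat skeletonization, so they are detected from
the segmented bitmask instead: 17 fixed shape descriptors feed a seeded
random forest, and per-frame turn flags are collapsed to one occurrence per
10-s window so a still, curled worm is not counted repeatedly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split
from skimage import measure
from skimage.morphology import convex_hull_image, skeletonize as _thin

from .track import KinematicsBin

DISPERSAL_MIN_SPEED_MM_S = 0.01
DISPERSAL_MAX_ANGVEL_DEG_S = 15.0

TURN_FEATURE_NAMES = (
    "area",
    "perimeter",
    "area_over_perimeter_sq",
    "major_axis_length",
    "minor_axis_length",
    "eccentricity",
    "solidity",
    "extent",
    "n_skeleton_endpoints",
    "skeleton_length",
    "endpoint_span_over_skeleton_length",
    "max_convexity_defect_depth",
    "circularity",
    "bbox_aspect_ratio",
    "hu_moment_1",
    "hu_moment_2",
    "mean_distance_transform",
)
N_TURN_FEATURES = len(TURN_FEATURE_NAMES)


def classify_dispersal(speed: float, angular_velocity: float) -> str:
    """Dispersal iff speed >= 0.01 mm/s and angular velocity < 15 deg/s
    ('minimum speed' read as inclusive, 'below' as strict)."""
    if speed >= DISPERSAL_MIN_SPEED_MM_S and angular_velocity < DISPERSAL_MAX_ANGVEL_DEG_S:
        return "dispersal"
    return "non_dispersal"


def is_quiescent(speed: float) -> bool:
    """Descriptive quiescence: speed below the dispersal floor."""
    return speed < DISPERSAL_MIN_SPEED_MM_S


def speed_angvel_density(bins: list[KinematicsBin],
                         speed_edges: np.ndarray | None = None,
                         angvel_edges: np.ndarray | None = None):
    """Normalized 2-D histogram of (speed, angular velocity) over 10-s bins.

    Returns ``(density, speed_edges, angvel_edges)``; density sums to 1.
    """
    if not bins:
        raise ValueError("need at least one kinematics bin")
    speeds = np.array([b.speed for b in bins])
    angs = np.array([b.angular_velocity for b in bins])
    if speed_edges is None:
        speed_edges = np.linspace(0.0, max(speeds.max(), 1e-9) * 1.001, 41)
    if angvel_edges is None:
        angvel_edges = np.linspace(0.0, max(angs.max(), 1e-9) * 1.001, 41)
    h, se, ae = np.histogram2d(speeds, angs, bins=[speed_edges, angvel_edges])
    total = h.sum()
    if total > 0:
        h = h / total
    return h, se, ae


def extract_turn_features(mask: np.ndarray) -> np.ndarray:
    """17 shape descriptors of a worm bitmask (fixed order).

    Chosen to separate elongated crawling shapes from self-contacting turn
    shapes: size and contour measures, ellipse fit, convexity (solidity,
    deepest convexity defect), skeleton topology (endpoint count, length,
    end-to-end span ratio), circularity, bounding-box aspect, the first two
    Hu moments, and the mean distance-transform value (thickness proxy).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("cannot extract features from an empty mask")
    lab = measure.label(mask, connectivity=2)
    region = max(measure.regionprops(lab), key=lambda r: r.area)
    crop = region.image
    area = float(region.area)
    perimeter = float(max(region.perimeter, 1e-9))

    # skeleton topology (no pruning; raw endpoint count is informative)
    skel = _thin(crop)
    skel_pix = np.argwhere(skel)
    skel_len = float(len(skel_pix))
    if skel_len > 0:
        nb = ndimage.convolve(skel.astype(int), np.ones((3, 3), int),
                              mode="constant") - skel.astype(int)
        endpoints = np.argwhere(skel & (nb == 1))
        n_end = float(len(endpoints))
        if len(endpoints) >= 2:
            span = max(
                np.linalg.norm(endpoints[i] - endpoints[j])
                for i in range(len(endpoints)) for j in range(i + 1, len(endpoints))
            )
        else:
            span = 0.0
    else:
        n_end, span = 0.0, 0.0

    # deepest convexity defect: farthest hull-interior pixel from the mask
    hull = convex_hull_image(crop)
    defect_region = hull & ~crop
    if defect_region.any():
        dist_to_mask = ndimage.distance_transform_edt(~crop)
        max_defect = float(dist_to_mask[defect_region].max())
    else:
        max_defect = 0.0

    dt = ndimage.distance_transform_edt(crop)
    bbox_h, bbox_w = crop.shape
    hu = region.moments_hu

    feats = np.array([
        area,
        perimeter,
        area / perimeter**2,
        float(region.axis_major_length),
        float(region.axis_minor_length),
        float(region.eccentricity),
        float(region.solidity),
        float(region.extent),
        n_end,
        skel_len,
        span / max(skel_len, 1.0),
        max_defect,
        4.0 * np.pi * area / perimeter**2,
        max(bbox_h, bbox_w) / max(min(bbox_h, bbox_w), 1),
        float(hu[0]),
        float(hu[1]),
        float(dt[crop].mean()),
    ])
    assert feats.shape == (N_TURN_FEATURES,)
    return feats


def turn_feature_matrix(masks) -> np.ndarray:
    return np.array([extract_turn_features(m) for m in masks])


class TurnClassifier(BaseEstimator, ClassifierMixin):
    """Random-forest turn detector on 17-feature shape vectors.

    ``fit`` takes a feature matrix (see :func:`extract_turn_features`) with
    binary labels (1 = turn: head or tail touching the body, or a U-shape);
    ``predict_score`` returns the forest's turn probability in [0, 1], which
    ``predict`` thresholds at ``score_threshold``.
    """

    def __init__(self, n_trees: int = 500, score_threshold: float = 0.5,
                 random_state: int = 0):
        self.n_trees = n_trees
        self.score_threshold = score_threshold
        self.random_state = random_state

    def fit(self, X: np.ndarray, y: np.ndarray) -> "TurnClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if len(np.unique(y)) < 2:
            raise ValueError("training set must contain both turn and non-turn shapes")
        self.forest_ = RandomForestClassifier(
            n_estimators=self.n_trees, random_state=self.random_state)
        self.forest_.fit(X, y)
        self.classes_ = self.forest_.classes_
        return self

    def predict_score(self, X: np.ndarray) -> np.ndarray:
        proba = self.forest_.predict_proba(np.asarray(X, dtype=float))
        return proba[:, list(self.forest_.classes_).index(1)]

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.predict_score(X) >= self.score_threshold).astype(int)

    def predict_mask(self, mask: np.ndarray) -> int:
        return int(self.predict(extract_turn_features(mask)[None, :])[0])


def train_turn_classifier(masks, labels, n_trees: int = 500, seed: int = 0,
                          test_fraction: float = 0.2):
    """Train a turn classifier on labeled bitmasks with a stratified
    held-out split; returns ``(classifier, held_out_accuracy)``."""
    X = turn_feature_matrix(masks)
    y = np.asarray(labels, dtype=int)
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=test_fraction, stratify=y, random_state=seed)
    clf = TurnClassifier(n_trees=n_trees, random_state=seed).fit(X_tr, y_tr)
    acc = float((clf.predict(X_te) == y_te).mean())
    return clf, acc


def bin_turns(turn_flags: np.ndarray, frame_rate: float,
              window_seconds: float = 10.0) -> np.ndarray:
    """Collapse per-frame turn flags to one 0/1 value per 10-s window
    (any flagged frame in the window counts once)."""
    flags = np.asarray(turn_flags).astype(bool)
    frames_per_win = max(1, int(round(window_seconds * frame_rate)))
    n_win = int(np.ceil(len(flags) / frames_per_win))
    return np.array([
        int(flags[w * frames_per_win:(w + 1) * frames_per_win].any())
        for w in range(n_win)
    ])


@dataclass
class BehaviorRecord:
    """State summary of one track over one 10-s bin."""

    track_id: int
    bin_index: int
    hat: float
    speed: float
    angular_velocity: float
    state: str          # "dispersal" | "non_dispersal"
    quiescent: bool
    turn_flag: int = 0


def records_from_kinematics(bins: list[KinematicsBin],
                            turn_flags_per_bin: np.ndarray | None = None) -> list[BehaviorRecord]:
    """Classify each kinematics bin into a behavior record."""
    records = []
    for i, b in enumerate(bins):
        turn = int(turn_flags_per_bin[i]) if turn_flags_per_bin is not None else 0
        records.append(BehaviorRecord(
            track_id=b.track_id, bin_index=b.bin_index, hat=b.hat,
            speed=b.speed, angular_velocity=b.angular_velocity,
            state=classify_dispersal(b.speed, b.angular_velocity),
            quiescent=is_quiescent(b.speed), turn_flag=turn,
        ))
    return records


def summarize_condition(records: list[BehaviorRecord],
                        hat_edges: np.ndarray) -> pd.DataFrame:
    """Time-resolved condition summary on an h.a.t. grid.

    Per time bin: dispersal fraction (over 10-s records), mean per-track
    speed (each track contributes its mean once), and turn frequency (mean
    turn occurrence per 10-s window) with its SEM across tracks.  Empty time
    bins give NaN rows.
    """
    hat_edges = np.asarray(hat_edges, dtype=float)
    rows = []
    for lo, hi in zip(hat_edges[:-1], hat_edges[1:]):
        sel = [r for r in records if lo <= r.hat < hi]
        if not sel:
            rows.append({"hat": lo, "dispersal_fraction": np.nan,
                         "mean_speed": np.nan, "turn_frequency": np.nan,
                         "turn_frequency_sem": np.nan, "n_records": 0})
            continue
        frac = np.mean([r.state == "dispersal" for r in sel])
        per_track_speed = pd.Series(
            [r.speed for r in sel], index=[r.track_id for r in sel]
        ).groupby(level=0).mean()
        per_track_turn = pd.Series(
            [r.turn_flag for r in sel], index=[r.track_id for r in sel]
        ).groupby(level=0).mean()
        n_tracks = len(per_track_turn)
        sem = float(per_track_turn.std(ddof=1) / np.sqrt(n_tracks)) if n_tracks > 1 else np.nan
        rows.append({
            "hat": lo,
            "dispersal_fraction": float(frac),
            "mean_speed": float(per_track_speed.mean()),
            "turn_frequency": float(per_track_turn.mean()),
            "turn_frequency_sem": sem,
            "n_records": len(sel),
        })
    return pd.DataFrame(rows)


def per_track_mean_speeds(records: list[BehaviorRecord]) -> pd.Series:
    """Mean speed per track (the per-track statistic compared between
    conditions with a Mann-Whitney test)."""
    s = pd.Series([r.speed for r in records], index=[r.track_id for r in records])
    return s.groupby(level=0).mean()
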