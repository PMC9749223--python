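"""End-to-end orchestration: simulate/read -> segment -> track -> skeletonize
-> posture -> behavior, with CSV outputs and a provenance sidecar.

Every stage parameter lives in one :class:`RunConfig` that round-trips
losslessly through YAML; defaults follow the printed analysis constants
(20-frame minimum tracks, 26-px skeletons, 10-s bins, 30-min settling
discard, k=200 posture clusters, k=3 meta-postures, dispersal thresholds
0.01 mm/s and 15 deg/s).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior, io, posture, segment, skeleton, track
from .simulate import SimConfig, make_turn_shape_dataset, simulate_plate


@dataclass
class RunConfig:
    """Full pipeline configuration (simulation input or image files)."""

    # input: either a simulation or a path to frames
    sim: SimConfig | None = None
    input_path: str | None = None
    pixel_size: float = 6.25          # um/px (used when reading files)
    frame_rate: float = 2.0           # fps
    start_time: float = 0.0           # s since transfer
    condition: str = "default"
    out_dir: str = "results"
    rng_seed: int = 0
    # segmentation
    threshold_sd: float = 5.0
    smoothing_sigma: float = 1.0
    worm_length: float = 48.0         # px; drives size selection + linking
    worm_width: float = 5.0
    background_stride: int = 1
    # tracking / kinematics
    max_link_distance: float | None = None   # default: worm_length
    min_track_frames: int = 20
    moving_only: bool = True
    bin_seconds: float = 10.0
    settle_hours: float = 0.5
    # skeleton
    min_skeleton_length: float = 26.0
    # posture syntax
    no_posture: bool = False
    library_k: int = 200
    meta_k: int = 3
    abundance_bin_hours: float = 1.0
    # turn classifier
    n_trees: int = 500
    turn_threshold: float = 0.5
    n_turn_training_shapes: int = 250  # per class

    def __post_init__(self):
        if isinstance(self.sim, dict):
            self.sim = SimConfig(**self.sim)

    def segment_params(self) -> segment.SegmentParams:
        return segment.SegmentParams.from_worm_geometry(
            self.worm_length, self.worm_width,
            threshold_sd=self.threshold_sd,
            smoothing_sigma=self.smoothing_sigma,
        )

    def link_distance(self) -> float:
        return self.max_link_distance if self.max_link_distance is not None else self.worm_length

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        if d["sim"] is not None:
            d["sim"]["bend_mode_amplitudes"] = list(d["sim"]["bend_mode_amplitudes"])
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        d = yaml.safe_load(text)
        if d.get("sim") is not None:
            d["sim"]["bend_mode_amplitudes"] = tuple(d["sim"]["bend_mode_amplitudes"])
        return cls(**d)


def _analyze_track(tr: track.Track, cfg: RunConfig, image_shape,
                   turn_clf: behavior.TurnClassifier, signal_for_frame=None):
    """Skeletons, postures, kinematics and turn flags for one track."""
    validations = {}
    for i, det in enumerate(tr.detections):
        full = det.full_mask(image_shape)
        try:
            validations[i] = skeleton.validate_skeleton(
                skeleton.skeletonize_mask(full), cfg.min_skeleton_length)
        except ValueError:
            continue
    oriented = skeleton.orient_track_skeletons(validations, tr.centroids,
                                               track_id=tr.track_id)
    postures = {}
    for sk in oriented:
        frame_idx = tr.detections[sk.frame_index].frame_index
        signal = signal_for_frame(frame_idx) if signal_for_frame else None
        try:
            postures[sk.frame_index] = skeleton.posture_angles(sk, intensity=signal)
        except ValueError:
            continue

    turn_scores = np.array([
        float(turn_clf.predict_score(
            behavior.extract_turn_features(det.mask)[None, :])[0])
        for det in tr.detections
    ])
    turn_flags = (turn_scores >= cfg.turn_threshold).astype(int)

    bins = track.compute_kinematics(tr, cfg.pixel_size, cfg.frame_rate,
                                    bin_seconds=cfg.bin_seconds,
                                    start_time_s=cfg.start_time)
    frames_per_bin = int(round(cfg.bin_seconds * cfg.frame_rate))
    turn_per_bin = behavior.bin_turns(turn_flags, cfg.frame_rate, cfg.bin_seconds)
    turn_per_bin = turn_per_bin[: len(bins)]
    records = behavior.records_from_kinematics(bins, turn_per_bin)
    return oriented, postures, turn_scores, bins, records, frames_per_bin


def run_pipeline(cfg: RunConfig) -> dict:
    """Run all stages; returns the in-memory result bundle and writes CSVs.

    Bundle keys: ``stack``, ``tracks``, ``result_table``, ``kinematics``,
    ``records``, ``summary``, and (unless ``no_posture``) ``library``,
    ``abundance``, ``eigenworms``, ``posture_vectors``.
    """
    if cfg.sim is None and cfg.input_path is None:
        raise ValueError("RunConfig needs either a simulation or an input_path")
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if cfg.sim is not None:
        stack, ground_truth = simulate_plate(cfg.sim)
        cfg.pixel_size = cfg.sim.pixel_size
        cfg.frame_rate = cfg.sim.frame_rate
        cfg.start_time = cfg.sim.start_time
        cfg.worm_length = cfg.sim.worm_length
        cfg.worm_width = cfg.sim.worm_width
    else:
        stack = io.read_frames(cfg.input_path, cfg.pixel_size, cfg.frame_rate,
                               start_time=cfg.start_time)
        ground_truth = None

    background = segment.estimate_background(stack, sample_stride=cfg.background_stride)
    detections = segment.segment_stack(stack, cfg.segment_params(),
                                       background=background)

    _signal_cache: dict[int, np.ndarray] = {}

    def signal_for_frame(f: int) -> np.ndarray:
        """Worm-positive intensity (background minus frame) for midline
        refinement; cached per frame."""
        if f not in _signal_cache:
            from scipy import ndimage as _ndi
            sig = np.clip(background - stack.frames[f].astype(float), 0, None)
            _signal_cache[f] = _ndi.gaussian_filter(sig, cfg.smoothing_sigma)
            if len(_signal_cache) > 64:
                _signal_cache.pop(next(iter(_signal_cache)))
        return _signal_cache[f]

    tracks = track.link_tracks(detections, cfg.link_distance())
    tracks = track.filter_tracks(tracks, cfg.min_track_frames,
                                 moving_only=cfg.moving_only,
                                 worm_length=cfg.worm_length)

    # turn classifier trained on synthetic labeled shapes at matched geometry
    masks, labels = make_turn_shape_dataset(
        cfg.n_turn_training_shapes, cfg.n_turn_training_shapes,
        seed=cfg.rng_seed, worm_length=cfg.worm_length, worm_width=cfg.worm_width)
    turn_clf, turn_acc = behavior.train_turn_classifier(
        masks, labels, n_trees=cfg.n_trees, seed=cfg.rng_seed)

    rows, kin_rows, all_records = [], [], []
    posture_vectors, posture_hat = [], []
    for tr in tracks:
        oriented, postures, turn_scores, bins, records, fpb = _analyze_track(
            tr, cfg, stack.image_shape, turn_clf, signal_for_frame)
        sk_by_frame = {sk.frame_index: sk for sk in oriented}
        for i, det in enumerate(tr.detections):
            sk = sk_by_frame.get(i)
            rows.append({
                "track_id": tr.track_id,
                "frame": det.frame_index,
                "x": det.centroid[0],
                "y": det.centroid[1],
                "area": det.area,
                "track_length": len(tr),
                "net_displacement": tr.net_displacement,
                "turn_score": turn_scores[i],
                "shape_rle": io.rle_encode(det.mask),
                "skeleton": io.encode_skeleton(sk.path) if sk else "",
                "head_source": sk.head_assignment_source if sk else "",
            })
        bins = track.discard_settling_period(bins, cfg.settle_hours)
        records = [r for r in records if r.hat >= cfg.settle_hours]
        kin_rows.extend(dataclasses.asdict(b) for b in bins)
        all_records.extend(records)
        # posture eligibility: per-bin kinematics filters + 5-s duration
        eligible_bins = [
            b for b in bins
            if posture.eligible_for_eigenworms(
                b.n_frames / cfg.frame_rate, b.speed, b.angular_velocity)
        ]
        eligible_idx = {b.bin_index for b in eligible_bins}
        for f, vec in postures.items():
            if (f // fpb) in eligible_idx:
                posture_vectors.append(vec)
                t = cfg.start_time + (tr.start_frame + f) / cfg.frame_rate
                posture_hat.append(t / 3600.0)

    result_table = pd.DataFrame(rows)
    kinematics = pd.DataFrame(kin_rows)
    hat_values = [r.hat for r in all_records]
    if hat_values:
        lo = np.floor(min(hat_values) / cfg.abundance_bin_hours) * cfg.abundance_bin_hours
        hi = max(hat_values) + cfg.abundance_bin_hours
        hat_edges = np.arange(lo, hi, cfg.abundance_bin_hours)
        if len(hat_edges) < 2:
            hat_edges = np.array([lo, lo + cfg.abundance_bin_hours])
    else:
        hat_edges = np.array([0.0, cfg.abundance_bin_hours])
    summary = behavior.summarize_condition(all_records, hat_edges)

    bundle = {
        "stack": stack,
        "ground_truth": ground_truth,
        "tracks": tracks,
        "result_table": result_table,
        "kinematics": kinematics,
        "records": all_records,
        "summary": summary,
        "turn_classifier": turn_clf,
        "turn_classifier_accuracy": turn_acc,
    }

    if not cfg.no_posture and len(posture_vectors) >= max(cfg.library_k, 24):
        X = np.array(posture_vectors)
        ew = posture.compute_eigenworms(X)
        lib = posture.build_posture_library(X, k=cfg.library_k,
                                            rng_seed=cfg.rng_seed)
        assignments = lib.predict(X)
        ab = posture.abundance_over_time(assignments, np.array(posture_hat),
                                         bin_hours=cfg.abundance_bin_hours,
                                         n_classes=lib.n_classes_)
        bundle.update(library=lib, eigenworms=ew, abundance=ab,
                      posture_vectors=X, posture_hat=np.array(posture_hat))

    write_results(bundle, cfg, out_dir)
    return bundle


def write_results(bundle: dict, cfg: RunConfig, out_dir) -> None:
    """Write the CSV outputs plus a provenance metadata sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle["result_table"].to_csv(out_dir / "result_table.csv", index=False)
    bundle["kinematics"].to_csv(out_dir / "kinematics.csv", index=False)
    pd.DataFrame([dataclasses.asdict(r) for r in bundle["records"]]).to_csv(
        out_dir / "behavior_records.csv", index=False)
    bundle["summary"].to_csv(out_dir / "behavior_summary.csv", index=False)
    if "library" in bundle:
        lib = bundle["library"]
        lib_df = pd.DataFrame(lib.centroids_,
                              columns=[f"theta{i}" for i in range(lib.centroids_.shape[1])])
        lib_df["mirror_partner"] = [lib.mirror_map_[i] for i in range(lib.k)]
        lib_df["class_id"] = lib.class_of_centroid_
        lib_df.to_csv(out_dir / "posture_library.csv", index_label="centroid")
        bundle["abundance"].raw.to_csv(out_dir / "posture_abundance_raw.csv")
        bundle["abundance"].zscore.to_csv(out_dir / "posture_abundance_zscore.csv")
        ew = bundle["eigenworms"]
        pd.DataFrame(ew.components_).assign(
            eigenvalue=ew.eigenvalues_,
            explained_variance_ratio=ew.explained_variance_ratio_,
        ).to_csv(out_dir / "eigenworms.csv", index_label="mode")
    io.write_metadata(out_dir, cfg.to_yaml(), cfg.rng_seed,
                      extra={"condition": cfg.condition,
                             "n_tracks": len(bundle["tracks"]),
                             "turn_classifier_accuracy": bundle["turn_classifier_accuracy"]})
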