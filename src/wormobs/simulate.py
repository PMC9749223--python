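"""Synthetic plate-timelapse simulator with full ground truth.

Emulates transmitted-light plate imaging of a *C. elegans* population:
dark worm-shaped objects on a bright noisy background, acquired as a
fixed-rate grayscale frame sequence with a known pixel size.  Each worm
carries a hidden behavioral state (quiescent / dispersal / dwelling, with
occasional turn events) driving its speed, heading persistence, and posture
amplitude; the midline evolves as two sinusoidal bend modes with a traveling
phase (the locomotion wave).  Everything the downstream pipeline estimates
(centroids, midlines, posture angles, states) is recorded as ground truth,
so every analysis stage has an oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import geometry
from .geometry import N_ANGLES, N_MIDLINE_POINTS

STATE_NAMES = ("quiescent", "dispersal", "dwelling", "turn")
QUIESCENT, DISPERSAL, DWELLING, TURN = range(4)

#: heading diffusion scale (rad / sqrt(s)) multiplied by (1 - persistence)
_HEADING_NOISE_SCALE = 2.0


def default_bend_modes(n_angles: int = N_ANGLES, spatial_freq: float = 1.5) -> np.ndarray:
    """Two unit-norm sinusoidal spatial bend modes over the body axis.

    Real crawling postures are dominated by a quadrature pair of roughly
    sinusoidal curvature profiles (~1.5 wavelengths along the body); a
    traveling phase between the pair produces the locomotion wave.
    Returns shape ``(2, n_angles)``.
    """
    s = np.linspace(0.0, 1.0, n_angles)
    m1 = np.sin(2 * np.pi * spatial_freq * s)
    m2 = np.cos(2 * np.pi * spatial_freq * s)
    m1 /= np.linalg.norm(m1)
    m2 /= np.linalg.norm(m2)
    return np.stack([m1, m2])


@dataclass
class SimConfig:
    """Simulation parameters.

    Geometry defaults match the target acquisition setup: 1024 x 1024 px at
    6.25 um/px (6.4 mm field of view), 2 frames/s, 8-min videos.  State
    kinematics are chosen to straddle the dispersal thresholds (0.01 mm/s,
    15 deg/s): quiescent worms barely move, dispersal is fast and straight,
    dwelling is slow-ish with frequent reorientation.
    """

    image_size: int = 1024
    pixel_size: float = 6.25          # um / px
    frame_rate: float = 2.0           # frames / s
    n_worms: int = 10
    duration: float = 480.0           # s (one 8-min video)
    worm_length: float = 48.0         # px (~0.3 mm dauer-scale)
    worm_width: float = 5.0           # px
    background_level: float = 200.0   # intensity units (bright field)
    noise_sd: float = 5.0
    worm_contrast: float = 60.0       # dark-on-bright; >= 5 x noise_sd
    # per-state per-second probability of leaving the state
    state_transition_rates: dict = field(
        default_factory=lambda: {"quiescent": 0.02, "dispersal": 0.02, "dwelling": 0.02}
    )
    speed_per_state: dict = field(
        default_factory=lambda: {"quiescent": 0.002, "dispersal": 0.03, "dwelling": 0.015}
    )  # mm / s
    heading_persistence_per_state: dict = field(
        default_factory=lambda: {"quiescent": 0.5, "dispersal": 0.98, "dwelling": 0.5}
    )  # 1 = frozen heading, 0 = fully diffusive
    bend_mode_amplitudes: tuple = (1.2, 1.2)  # radians, per mode at amplitude scale 1
    posture_amplitude_per_state: dict = field(
        default_factory=lambda: {"quiescent": 0.3, "dispersal": 0.7, "dwelling": 1.0}
    )  # dauer-stiff quiescence = shallow bends
    undulation_hz: float = 0.3        # traveling-wave temporal frequency
    turn_probability: float = 0.0     # per-second probability of a turn event
    turn_duration: float = 2.0        # s
    initial_state: str | None = None  # force all worms' starting state
    start_time: float = 0.0           # s since transfer (h.a.t. origin)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size <= 0:
            raise ValueError("image_size must be positive")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.worm_length < 26:
            raise ValueError("worm_length must be >= 26 px for valid skeletons")
        if self.worm_length >= self.image_size:
            raise ValueError("worm_length must be smaller than image_size")
        for d in (self.state_transition_rates, self.speed_per_state,
                  self.heading_persistence_per_state, self.posture_amplitude_per_state):
            if any(v < 0 for v in d.values()):
                raise ValueError("rates, speeds and amplitudes must be >= 0")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.frame_rate))

    def speed_px_per_frame(self, state: str) -> float:
        """Convert a state's speed (mm/s) to px/frame."""
        return self.speed_per_state[state] * 1000.0 / self.pixel_size / self.frame_rate

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class FrameStack:
    """An ordered, calibrated grayscale image sequence."""

    frames: np.ndarray                # (n_frames, H, W)
    pixel_size: float                 # um / px
    frame_rate: float                 # frames / s
    timestamps: np.ndarray            # s since transfer, strictly increasing

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n, H, W) array")
        if len(self.timestamps) != len(self.frames):
            raise ValueError("one timestamp per frame required")
        if len(self.timestamps) > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, i):
        return self.frames[i]

    @property
    def image_shape(self) -> tuple:
        return self.frames.shape[1:]

    @property
    def field_of_view_um(self) -> tuple:
        """Physical extent (width, height) of the imaged field in um."""
        h, w = self.frames.shape[1:]
        return (w * self.pixel_size, h * self.pixel_size)


class GroundTruth:
    """Per-frame, per-worm simulator ground truth.

    Arrays are indexed ``[frame, worm]``; worms that have wandered outside
    the field of view keep their (off-screen) trajectory, with
    ``fully_in_view`` marking frames where the whole midline is on-screen.
    """

    def __init__(self, n_frames: int, n_worms: int):
        self.centroids = np.zeros((n_frames, n_worms, 2))
        self.midlines = np.zeros((n_frames, n_worms, N_MIDLINE_POINTS, 2))
        self.angles = np.zeros((n_frames, n_worms, N_ANGLES))
        self.states = np.zeros((n_frames, n_worms), dtype=int)
        self.fully_in_view = np.zeros((n_frames, n_worms), dtype=bool)

    @property
    def n_frames(self) -> int:
        return self.centroids.shape[0]

    @property
    def n_worms(self) -> int:
        return self.centroids.shape[1]

    def state_names(self) -> np.ndarray:
        return np.array(STATE_NAMES, dtype=object)[self.states]

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format table: one row per (frame, worm)."""
        rows = []
        for f in range(self.n_frames):
            for w in range(self.n_worms):
                row = {
                    "frame": f,
                    "worm_id": w,
                    "x": self.centroids[f, w, 0],
                    "y": self.centroids[f, w, 1],
                    "state": STATE_NAMES[self.states[f, w]],
                    "fully_in_view": self.fully_in_view[f, w],
                }
                for i in range(N_MIDLINE_POINTS):
                    row[f"mx{i}"] = self.midlines[f, w, i, 0]
                    row[f"my{i}"] = self.midlines[f, w, i, 1]
                for i in range(N_ANGLES):
                    row[f"theta{i}"] = self.angles[f, w, i]
                rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _step_state(state: int, cfg: SimConfig, rng: np.random.Generator) -> int:
    """One per-frame Markov step over the three locomotor states."""
    name = STATE_NAMES[state]
    p_leave = min(1.0, cfg.state_transition_rates[name] / cfg.frame_rate)
    if rng.random() < p_leave:
        others = [s for s in range(3) if s != state]
        return int(rng.choice(others))
    return state


def simulate_state_sequence(cfg: SimConfig, n_steps: int, seed: int | None = None) -> np.ndarray:
    """Markov state sequence alone (no rendering), for occupancy checks."""
    rng = np.random.default_rng(cfg.rng_seed if seed is None else seed)
    states = np.empty(n_steps, dtype=int)
    s = int(rng.integers(0, 3))
    for i in range(n_steps):
        states[i] = s
        s = _step_state(s, cfg, rng)
    return states


def _disk_offsets(radius: float) -> np.ndarray:
    r = int(np.ceil(radius))
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    keep = yy**2 + xx**2 <= radius**2
    return np.stack([xx[keep], yy[keep]], axis=1)  # (K, 2) as (dx, dy)


def _stamp_curve(mask: np.ndarray, points: np.ndarray, radius: float) -> None:
    """Mark all pixels within ``radius`` of the densely sampled curve."""
    if len(points) == 0:
        return
    offs = _disk_offsets(radius)
    pts = np.round(points).astype(int)
    coords = (pts[:, None, :] + offs[None, :, :]).reshape(-1, 2)
    h, w = mask.shape
    keep = (
        (coords[:, 0] >= 0) & (coords[:, 0] < w)
        & (coords[:, 1] >= 0) & (coords[:, 1] < h)
    )
    coords = coords[keep]
    mask[coords[:, 1], coords[:, 0]] = True


def _dense_midline(midline: np.ndarray, step: float = 0.5) -> np.ndarray:
    n = max(2, int(np.ceil(geometry.arc_length(midline) / step)) + 1)
    return geometry.resample_midline(midline, n=n)


def render_worms(midlines, image_size: int, cfg: SimConfig,
                 rng: np.random.Generator) -> np.ndarray:
    """Render one frame: bright background, additive noise, dark worms."""
    canvas = np.full((image_size, image_size), float(cfg.background_level))
    mask = np.zeros((image_size, image_size), dtype=bool)
    for ml in midlines:
        # skip worms entirely off-screen (with margin for body width)
        m = cfg.worm_width
        if (ml[:, 0].max() < -m or ml[:, 0].min() > image_size + m
                or ml[:, 1].max() < -m or ml[:, 1].min() > image_size + m):
            continue
        _stamp_curve(mask, _dense_midline(ml), cfg.worm_width / 2.0)
    canvas[mask] -= cfg.worm_contrast
    canvas += rng.normal(0.0, cfg.noise_sd, canvas.shape)
    return np.clip(np.round(canvas), 0, 255).astype(np.uint8)


def _omega_profile(total_bend: float, n_angles: int = N_ANGLES) -> np.ndarray:
    """Uniform-curvature bend profile with the given total turning angle."""
    return np.full(n_angles, total_bend / n_angles)


class _Worm:
    """Internal per-worm simulation state."""

    def __init__(self, cfg: SimConfig, rng: np.random.Generator):
        margin = min(cfg.worm_length, 0.4 * cfg.image_size)
        self.pos = rng.uniform(margin, cfg.image_size - margin, size=2)
        self.heading = rng.uniform(-np.pi, np.pi)
        if cfg.initial_state is not None:
            self.state = STATE_NAMES.index(cfg.initial_state)
        else:
            self.state = int(rng.integers(0, 3))
        self.phase = rng.uniform(0, 2 * np.pi)
        self.turn_frames_left = 0
        self.turn_profile = None

    def angles(self, cfg: SimConfig, modes: np.ndarray) -> np.ndarray:
        if self.turn_frames_left > 0:
            return self.turn_profile
        amp = cfg.posture_amplitude_per_state[STATE_NAMES[self.state]]
        a1, a2 = cfg.bend_mode_amplitudes
        return amp * (a1 * np.cos(self.phase) * modes[0]
                      + a2 * np.sin(self.phase) * modes[1])


def simulate_plate(cfg: SimConfig) -> tuple[FrameStack, GroundTruth]:
    """Run the simulation; deterministic given ``cfg.rng_seed``.

    Worm trajectories continue off-screen (reflecting only at an arena 25%
    larger than the field of view), so worms leave and re-enter the image.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    n_frames = cfg.n_frames
    modes = default_bend_modes()
    seg_len = cfg.worm_length / (N_MIDLINE_POINTS - 1)
    arena_lo = -0.25 * cfg.image_size
    arena_hi = 1.25 * cfg.image_size

    worms = [_Worm(cfg, rng) for _ in range(cfg.n_worms)]
    gt = GroundTruth(n_frames, cfg.n_worms)
    frames = np.empty((n_frames, cfg.image_size, cfg.image_size), dtype=np.uint8)
    timestamps = cfg.start_time + np.arange(n_frames) / cfg.frame_rate

    for f in range(n_frames):
        midlines = []
        for w, worm in enumerate(worms):
            state_name = STATE_NAMES[worm.state]
            label = TURN if worm.turn_frames_left > 0 else worm.state

            ang = worm.angles(cfg, modes)
            # body axis points along the heading, head first
            ml = geometry.midline_from_angles(
                ang, seg_len, head=(0.0, 0.0), heading=worm.heading + np.pi
            )
            ml = ml - ml.mean(axis=0) + worm.pos

            gt.centroids[f, w] = worm.pos
            gt.midlines[f, w] = ml
            gt.angles[f, w] = ang
            gt.states[f, w] = label
            gt.fully_in_view[f, w] = bool(
                np.all((ml >= 0) & (ml < cfg.image_size))
            )
            midlines.append(ml)

            # --- advance dynamics ---
            speed_px = cfg.speed_px_per_frame(state_name)
            if worm.turn_frames_left > 0:
                speed_px *= 0.2  # turning worms barely translate
                worm.turn_frames_left -= 1
            worm.pos = worm.pos + speed_px * np.array(
                [np.cos(worm.heading), np.sin(worm.heading)]
            )
            # reflect at the arena boundary so worms revisit the field
            for d, flip in ((0, "x"), (1, "y")):
                if worm.pos[d] < arena_lo:
                    worm.pos[d] = 2 * arena_lo - worm.pos[d]
                    worm.heading = (np.pi - worm.heading) if flip == "x" else -worm.heading
                elif worm.pos[d] > arena_hi:
                    worm.pos[d] = 2 * arena_hi - worm.pos[d]
                    worm.heading = (np.pi - worm.heading) if flip == "x" else -worm.heading
            rho = cfg.heading_persistence_per_state[state_name]
            sd = (1.0 - rho) * _HEADING_NOISE_SCALE / np.sqrt(cfg.frame_rate)
            worm.heading = float(geometry.wrap_angle(worm.heading + rng.normal(0.0, sd)))
            if worm.state != QUIESCENT:
                worm.phase = (worm.phase + 2 * np.pi * cfg.undulation_hz / cfg.frame_rate) % (2 * np.pi)
            worm.state = _step_state(worm.state, cfg, rng)
            # turn events
            if worm.turn_frames_left == 0 and cfg.turn_probability > 0:
                if rng.random() < cfg.turn_probability / cfg.frame_rate:
                    worm.turn_frames_left = max(1, int(round(cfg.turn_duration * cfg.frame_rate)))
                    total = np.deg2rad(rng.uniform(200, 360)) * rng.choice([-1, 1])
                    worm.turn_profile = _omega_profile(total)

        frames[f] = render_worms(midlines, cfg.image_size, cfg, rng)

    stack = FrameStack(frames, cfg.pixel_size, cfg.frame_rate, timestamps)
    return stack, gt


def render_turn_shape(bend_profile: np.ndarray, worm_length: float = 48.0,
                      worm_width: float = 5.0) -> np.ndarray:
    """Render a single worm bitmask from a bend (intersegment-angle) profile.

    Used to build labeled shape sets for the turn classifier: strongly bent
    profiles produce self-contacting (omega) or U-shaped blobs, shallow
    profiles produce elongated blobs.
    """
    bend = np.asarray(bend_profile, dtype=float)
    seg_len = worm_length / (len(bend) + 1)
    ml = geometry.midline_from_angles(bend, seg_len)
    pad = worm_width + 2
    ml = ml - ml.min(axis=0) + pad
    h = int(np.ceil(ml[:, 1].max() + pad))
    w = int(np.ceil(ml[:, 0].max() + pad))
    mask = np.zeros((h, w), dtype=bool)
    _stamp_curve(mask, _dense_midline(ml), worm_width / 2.0)
    return mask


def make_turn_shape_dataset(n_turn: int, n_nonturn: int, seed: int = 0,
                            worm_length: float = 48.0, worm_width: float = 5.0):
    """Labeled bitmask set for turn-classifier training.

    Turns follow the annotation rule (head or tail touching the body, or a
    U-shape with head and tail pointing the same way): total bend sampled in
    [170, 360] degrees plus mode wiggle.  Non-turns are locomotion-wave
    postures with near-zero net bend.  Returns ``(masks, labels)`` with
    label 1 = turn.
    """
    rng = np.random.default_rng(seed)
    modes = default_bend_modes()
    masks, labels = [], []
    for _ in range(n_turn):
        total = np.deg2rad(rng.uniform(170, 360)) * rng.choice([-1, 1])
        wiggle = 0.3 * (rng.normal() * modes[0] + rng.normal() * modes[1])
        masks.append(render_turn_shape(_omega_profile(total) + wiggle,
                                       worm_length, worm_width))
        labels.append(1)
    for _ in range(n_nonturn):
        phase = rng.uniform(0, 2 * np.pi)
        amp = rng.uniform(0.2, 1.3)
        prof = amp * 1.2 * (np.cos(phase) * modes[0] + np.sin(phase) * modes[1])
        masks.append(render_turn_shape(prof, worm_length, worm_width))
        labels.append(0)
    return masks, np.array(labels)
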