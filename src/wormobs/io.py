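"""File I/O: image stacks, run-length-encoded masks, result tables.

Frames are read from multi-page TIFF files or numbered PNG sequences and
carried with their calibration (pixel size, frame rate).  Segmented shapes
are serialized as run-length-encoded strings and skeletons as ordered
``x:y;`` pixel lists, so every result table is plain CSV.
"""

from __future__ import annotations

import hashlib
import json
import re
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .simulate import FrameStack


def write_frames(stack: FrameStack, path) -> None:
    """Write a stack as a multi-page TIFF (.tif) or a numbered PNG sequence
    (path treated as a directory)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, stack.frames, photometric="minisblack")
    else:
        path.mkdir(parents=True, exist_ok=True)
        for i, frame in enumerate(stack.frames):
            iio.imwrite(path / f"frame_{i:06d}.png", frame)


def read_frames(path, pixel_size: float | None, frame_rate: float | None,
                start_time: float = 0.0) -> FrameStack:
    """Read a TIFF stack or numbered PNG directory into a calibrated stack.

    Calibration must be supplied; a missing value raises an error naming the
    field.  PNG sequences must be gap-free in their numbering and all frames
    must share one image size.
    """
    if pixel_size is None:
        raise ValueError("missing calibration: pixel_size")
    if frame_rate is None:
        raise ValueError("missing calibration: frame_rate")
    path = Path(path)
    if path.is_dir():
        files = sorted(path.glob("*.png"))
        if not files:
            raise FileNotFoundError(f"no PNG frames in {path}")
        indices = []
        for f in files:
            m = re.search(r"(\d+)", f.stem)
            if not m:
                raise ValueError(f"cannot parse frame index from {f.name}")
            indices.append(int(m.group(1)))
        order = np.argsort(indices)
        indices = [indices[i] for i in order]
        files = [files[i] for i in order]
        expected = list(range(indices[0], indices[0] + len(indices)))
        missing = sorted(set(expected) - set(indices))
        if missing:
            raise ValueError(f"gap in PNG numbering; missing indices {missing}")
        frames = [iio.imread(f) for f in files]
        shapes = {f.shape for f in frames}
        if len(shapes) > 1:
            raise ValueError(f"mixed image sizes in sequence: {sorted(shapes)}")
        frames = np.stack(frames)
    else:
        frames = tifffile.imread(path)
        if frames.ndim == 2:
            frames = frames[None]
    timestamps = start_time + np.arange(len(frames)) / frame_rate
    return FrameStack(frames, pixel_size, frame_rate, timestamps)


def rle_encode(mask: np.ndarray) -> str:
    """Run-length encode a boolean mask (row-major): 'H,W:start-len;...'."""
    mask = np.asarray(mask, dtype=bool)
    flat = mask.ravel()
    padded = np.concatenate([[False], flat, [False]])
    changes = np.flatnonzero(padded[1:] != padded[:-1])
    starts, ends = changes[::2], changes[1::2]
    runs = ";".join(f"{s}-{e - s}" for s, e in zip(starts, ends))
    return f"{mask.shape[0]},{mask.shape[1]}:{runs}"


def rle_decode(s: str) -> np.ndarray:
    """Inverse of :func:`rle_encode`."""
    header, _, runs = s.partition(":")
    h, w = (int(v) for v in header.split(","))
    flat = np.zeros(h * w, dtype=bool)
    if runs:
        for run in runs.split(";"):
            start, length = (int(v) for v in run.split("-"))
            flat[start:start + length] = True
    return flat.reshape(h, w)


def encode_skeleton(path_xy: np.ndarray) -> str:
    """Ordered pixel list as 'x:y;x:y;...' (head first)."""
    return ";".join(f"{x:g}:{y:g}" for x, y in np.asarray(path_xy))


def decode_skeleton(s: str) -> np.ndarray:
    if not s:
        return np.empty((0, 2))
    return np.array([[float(v) for v in p.split(":")] for p in s.split(";")])


def config_hash(config_text: str) -> str:
    return hashlib.sha256(config_text.encode()).hexdigest()[:16]


def write_metadata(out_dir, config_text: str, seed: int, extra: dict | None = None) -> Path:
    """Provenance sidecar: config hash, seed, package version."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta = {
        "config_hash": config_hash(config_text),
        "rng_seed": seed,
        "wormobs_version": __version__,
    }
    meta.update(extra or {})
    p = out_dir / "metadata.json"
    p.write_text(json.dumps(meta, indent=2))
    return p
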