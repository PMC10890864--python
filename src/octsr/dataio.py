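"""Reading and writing image stacks, manifests and reports.

The on-disk format is directories of losslessly compressed grayscale PNG (or
TIFF) frames.  In memory every image lives on the [-1, 1] float scale; the
integer file representation maps 0 -> -1.0 and the dtype maximum -> +1.0.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import imageio.v3 as iio
import numpy as np

IMAGE_SUFFIXES = (".png", ".tif", ".tiff")


def to_float(arr: np.ndarray) -> np.ndarray:
    """Integer image -> float32 in [-1, 1]."""
    if arr.dtype.kind == "f":
        return arr.astype(np.float32)
    info = np.iinfo(arr.dtype)
    return (arr.astype(np.float32) / info.max) * 2.0 - 1.0


def from_float(arr: np.ndarray, bit_depth: int = 16) -> np.ndarray:
    """Float image in [-1, 1] -> uint8/uint16; out-of-range values clip."""
    if bit_depth not in (8, 16):
        raise ValueError("bit_depth must be 8 or 16")
    if arr.min() < -1.0 or arr.max() > 1.0:
        warnings.warn("values outside [-1, 1] clipped on save", stacklevel=2)
        arr = np.clip(arr, -1.0, 1.0)
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    maxv = np.iinfo(dtype).max
    return np.round((arr + 1.0) * 0.5 * maxv).astype(dtype)


def load_image(path) -> np.ndarray:
    arr = iio.imread(path)
    if arr.ndim == 3:  # collapse accidental RGB
        arr = arr.mean(axis=-1).astype(arr.dtype)
    return to_float(arr)


def save_image(img: np.ndarray, path, bit_depth: int = 16) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, from_float(np.asarray(img), bit_depth))
    return path


def load_sequence(directory) -> np.ndarray:
    """Load a (T, H, W) float32 clip from lexicographically sorted frames."""
    directory = Path(directory)
    files = sorted(p for p in directory.iterdir() if p.suffix.lower() in IMAGE_SUFFIXES)
    if not files:
        raise FileNotFoundError(f"no image frames in {directory}")
    frames = [load_image(p) for p in files]
    shapes = {f.shape for f in frames}
    if len(shapes) != 1:
        raise ValueError(f"mixed frame dimensions in {directory}: {shapes}")
    return np.stack(frames)


def save_sequence(seq: np.ndarray, directory, bit_depth: int = 16) -> list[Path]:
    seq = np.asarray(seq)
    if seq.ndim != 3:
        raise ValueError("sequence must be (T, H, W)")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    return [save_image(frame, directory / f"frame_{t:03d}.png", bit_depth)
            for t, frame in enumerate(seq)]


def write_json(obj, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonify))
    return path


def read_json(path):
    return json.loads(Path(path).read_text())


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def list_images(directory) -> list[Path]:
    """All image files under ``directory`` (recursive), sorted by path."""
    directory = Path(directory)
    return sorted(p for p in directory.rglob("*") if p.suffix.lower() in IMAGE_SUFFIXES)
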