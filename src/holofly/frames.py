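"""Hologram frame container and streaming frame I/O.

Frames are stored on disk either as one multi-page TIFF or as a directory of
numbered single-frame TIFF/PNG images.  In memory a frame is a float grid in
``[0, 1]``: 8-bit input is divided by 255, 16-bit by 65535, float input is
passed through unchanged.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import imageio.v3 as iio
import numpy as np
import tifffile

__all__ = ["HologramFrame", "read_frames", "write_frames"]


@dataclass
class HologramFrame:
    """One recorded (or simulated) hologram: a 2D intensity grid."""

    pixels: np.ndarray
    index: int
    t_s: float = 0.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("a hologram frame must be a 2D grid")


def _normalize(raw: np.ndarray) -> np.ndarray:
    if raw.dtype == np.uint8:
        return raw.astype(np.float64) / 255.0
    if raw.dtype == np.uint16:
        return raw.astype(np.float64) / 65535.0
    return np.asarray(raw, dtype=np.float64)


def _numeric_sort_key(path: Path) -> tuple:
    parts = re.split(r"(\d+)", path.name)
    return tuple(int(p) if p.isdigit() else p for p in parts)


def read_frames(path: str | Path, fps: float = 100.0) -> Iterator[HologramFrame]:
    """Yield frames in index order with constant memory in the frame count.

    ``path`` may be a multi-page TIFF file or a directory containing
    numbered ``.tif``/``.tiff``/``.png`` frames (sorted numerically).
    """
    path = Path(path)
    dt = 1.0 / fps
    if path.is_dir():
        files = sorted(
            (p for p in path.iterdir() if p.suffix.lower() in {".tif", ".tiff", ".png"}),
            key=_numeric_sort_key,
        )
        if not files:
            raise FileNotFoundError(f"no TIFF/PNG frames found in {path}")
        shape = None
        for i, f in enumerate(files):
            try:
                raw = iio.imread(f)
            except Exception as exc:  # pragma: no cover - backend specific
                raise OSError(f"unreadable frame {i}: {f}") from exc
            if shape is None:
                shape = raw.shape
            elif raw.shape != shape:
                raise ValueError(
                    f"frame {i} has shape {raw.shape}, expected {shape}"
                )
            yield HologramFrame(_normalize(raw), index=i, t_s=i * dt)
    elif path.is_file():
        with tifffile.TiffFile(path) as tif:
            shape = None
            for i, page in enumerate(tif.pages):
                raw = page.asarray()
                if shape is None:
                    shape = raw.shape
                elif raw.shape != shape:
                    raise ValueError(
                        f"frame {i} has shape {raw.shape}, expected {shape}"
                    )
                yield HologramFrame(_normalize(raw), index=i, t_s=i * dt)
    else:
        raise FileNotFoundError(f"no such frame source: {path}")


def write_frames(
    path: str | Path,
    frames: Iterable[HologramFrame],
    bit_depth: int = 16,
) -> Path:
    """Write frames as a multi-page TIFF, quantized to the given bit depth."""
    path = Path(path)
    if bit_depth == 16:
        scale, dtype = 65535.0, np.uint16
    elif bit_depth == 8:
        scale, dtype = 255.0, np.uint8
    else:
        raise ValueError("bit_depth must be 8 or 16")
    with tifffile.TiffWriter(path) as tif:
        for frame in frames:
            data = np.clip(frame.pixels, 0.0, 1.0)
            tif.write((data * scale + 0.5).astype(dtype), contiguous=False)
    return path
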