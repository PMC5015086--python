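"""Long-term behavior statistics and rapid-motion event extraction.

Everything here consumes corrected 3D trajectories of *single* flies (the
tracking stage has already excluded overlap spans): spatial occupancy PDFs
on millimeter-scale bins, the distribution of distance to the closest
neighbor, three-state speed ethograms (resting / walking / flying), and
detection plus in-focus rendering of rapid vertical motions such as falls
and takeoffs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage

from .frames import HologramFrame
from .optics import OpticsConfig, propagate
from .synth import ArenaBox
from .track3d import Track3D

__all__ = [
    "EthogramConfig",
    "EventRecord",
    "spatial_pdf",
    "closest_distance_pdf",
    "ethogram",
    "detect_rapid_vertical",
    "render_event",
]

log = logging.getLogger(__name__)

ETHOGRAM_STATES = ("resting", "walking", "flying")


@dataclass(frozen=True)
class EthogramConfig:
    """Two speed thresholds (mm/s) defining the three motion levels.

    Defaults were calibrated against the synthetic state model (resting
    jitter well below 1 mm/s; walking below ~15 mm/s; flight above), not
    taken from any measured dataset.
    """

    rest_max_mm_s: float = 1.0
    walk_max_mm_s: float = 15.0

    def __post_init__(self) -> None:
        if not 0 < self.rest_max_mm_s < self.walk_max_mm_s:
            raise ValueError("need 0 < rest_max < walk_max")


@dataclass
class EventRecord:
    """One rapid-vertical-motion event on one track."""

    track_id: int
    start_frame: int
    end_frame: int  # inclusive
    peak_speed_mm_s: float
    kind: str = "rapid_vertical"
    clip_path: str | None = None


def spatial_pdf(
    tracks: list[Track3D],
    arena: ArenaBox,
    bin_mm: tuple[float, float, float] = (0.3, 0.3, 1.0),
) -> tuple[np.ndarray, list[np.ndarray]]:
    """3D occupancy probability over the arena.

    Histograms every per-frame position into bins of ``bin_mm`` (default
    0.3 x 0.3 x 1 mm) and normalizes to total mass 1.  Positions outside
    the arena are clipped into the boundary bins (counted and logged).
    Returns ``(pdf, [x_edges_m, y_edges_m, z_edges_m])``.
    """
    pos = np.concatenate([t.positions_m for t in tracks], axis=0)
    if pos.size == 0:
        raise ValueError("no positions to histogram")
    lo, hi = arena.lo, arena.hi
    outside = np.any((pos < lo) | (pos > hi), axis=1).sum()
    if outside:
        log.info("spatial_pdf: clipped %d positions outside the arena", outside)
    eps = 1e-12
    pos = np.clip(pos, lo, hi - eps)
    edges = [
        np.arange(lo[i], hi[i] + bin_mm[i] * 1e-3, bin_mm[i] * 1e-3)
        for i in range(3)
    ]
    hist, edges = np.histogramdd(pos, bins=edges)
    return hist / hist.sum(), list(edges)


def closest_distance_pdf(
    per_frame_positions: dict[int, np.ndarray],
    bin_mm: float = 1.0,
    max_mm: float | None = None,
) -> pd.DataFrame:
    """Density of the distance to the closest simultaneous neighbor.

    Each fly in each frame with at least two flies contributes its nearest
    neighbor Euclidean distance; frames with fewer flies are skipped.
    Returns a dataframe ``(bin_center_mm, density)`` normalized so the
    density integrates to 1 over distance in mm.
    """
    dists = []
    for frame in sorted(per_frame_positions):
        pos = np.asarray(per_frame_positions[frame], dtype=float)
        if pos.shape[0] < 2:
            continue
        d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=2)
        np.fill_diagonal(d, np.inf)
        dists.extend(d.min(axis=1) * 1e3)
    if not dists:
        log.warning("closest_distance_pdf: no frame had two or more flies")
        return pd.DataFrame({"bin_center_mm": [], "density": []})
    dists = np.asarray(dists)
    top = max_mm if max_mm is not None else dists.max() + bin_mm
    edges = np.arange(0.0, top + bin_mm, bin_mm)
    counts, edges = np.histogram(dists, bins=edges)
    density = counts / (counts.sum() * bin_mm)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return pd.DataFrame({"bin_center_mm": centers, "density": density})


def ethogram(
    track: Track3D,
    cfg: EthogramConfig | None = None,
    min_dwell_frames: int = 1,
) -> np.ndarray:
    """Per-frame motion state from the corrected speed series.

    ``resting`` at or below ``rest_max``, ``walking`` at or below
    ``walk_max``, ``flying`` above.  With ``min_dwell_frames > 1`` a
    majority filter of that window suppresses single-frame flicker.  The
    three states partition every frame.
    """
    cfg = cfg or EthogramConfig()
    if track.speed_mm_s is None:
        raise ValueError("track has no speed series; run velocity_correct")
    codes = np.digitize(
        track.speed_mm_s, [cfg.rest_max_mm_s, cfg.walk_max_mm_s], right=True
    )
    if min_dwell_frames > 1:
        def majority(window: np.ndarray) -> int:
            return int(np.bincount(window.astype(int), minlength=3).argmax())

        codes = ndimage.generic_filter(
            codes.astype(float), majority, size=min_dwell_frames, mode="nearest"
        ).astype(int)
    return np.array([ETHOGRAM_STATES[c] for c in codes], dtype=object)


def _vertical_speed(track: Track3D, axis: str) -> np.ndarray:
    comp = {"x": track.x_m, "y": track.y_m, "z": track.z_m}[axis]
    v = np.gradient(comp, track.t_s) * 1e3  # mm/s
    return v


def detect_rapid_vertical(
    tracks: list[Track3D],
    vz_thresh_mm_s: float = 50.0,
    min_frames: int = 3,
    vertical_axis: str = "y",
) -> list[EventRecord]:
    """Spans of sustained rapid vertical motion (falls, takeoffs).

    A contiguous run of at least ``min_frames`` frames with
    ``|v_vertical| >= vz_thresh_mm_s`` becomes one event; boundaries sit at
    the threshold crossings.  Gravity points along +y in this package's
    arena frame, so the default vertical axis is ``y``.
    """
    events: list[EventRecord] = []
    for track in tracks:
        v = _vertical_speed(track, vertical_axis)
        above = np.abs(v) >= vz_thresh_mm_s
        start = None
        for k in range(len(above) + 1):
            if k < len(above) and above[k]:
                if start is None:
                    start = k
            elif start is not None:
                if k - start >= min_frames:
                    events.append(
                        EventRecord(
                            track_id=track.track_id,
                            start_frame=int(track.frames[start]),
                            end_frame=int(track.frames[k - 1]),
                            peak_speed_mm_s=float(
                                np.abs(v[start:k]).max()
                            ),
                        )
                    )
                start = None
    events.sort(key=lambda e: (e.start_frame, e.track_id))
    return events


def render_event(
    event: EventRecord,
    frames: dict[int, HologramFrame],
    track: Track3D,
    optics: OpticsConfig,
    crop_px: int = 150,
    scale_bar_mm: float = 2.0,
    out_dir: str | Path | None = None,
) -> list[np.ndarray]:
    """In-focus reconstructions of the event span, inverted grayscale.

    Each frame in the span is cropped around the fly, numerically refocused
    to that frame's depth, and written as the inverted reconstructed
    amplitude (dark fly on a white background) with a scale bar of
    ``scale_bar_mm``.  Frames with no depth estimate are skipped with a log
    entry.  Returns the rendered 8-bit images and optionally writes PNGs.
    """
    frame_to_idx = {int(f): i for i, f in enumerate(track.frames)}
    images: list[np.ndarray] = []
    pitch = optics.pixel_pitch_m
    for f in range(event.start_frame, event.end_frame + 1):
        if f not in frame_to_idx or f not in frames:
            log.info("render_event: frame %d unavailable, skipped", f)
            continue
        i = frame_to_idx[f]
        z = track.z_m[i]
        if np.isnan(z):
            log.info("render_event: frame %d has no depth, skipped", f)
            continue
        pixels = frames[f].pixels.astype(float)
        contrast = pixels - pixels.mean()
        r = int(round(track.y_m[i] / pitch))
        c = int(round(track.x_m[i] / pitch))
        n = crop_px
        crop = np.zeros((n, n))
        r0, c0 = r - n // 2, c - n // 2
        rs0, rs1 = max(r0, 0), min(r0 + n, pixels.shape[0])
        cs0, cs1 = max(c0, 0), min(c0 + n, pixels.shape[1])
        crop[rs0 - r0 : rs1 - r0, cs0 - c0 : cs1 - c0] = contrast[
            rs0:rs1, cs0:cs1
        ]
        amp = np.abs(propagate(crop.astype(complex), optics, -float(z)).values)
        rng = amp.max() - amp.min()
        norm = (amp - amp.min()) / rng if rng > 0 else amp * 0.0
        img = 1.0 - norm  # dark fly, white background
        bar_px = int(round(scale_bar_mm * 1e-3 / pitch))
        img[-8:-4, 4 : 4 + min(bar_px, n - 8)] = 0.0
        img8 = (img * 255).astype(np.uint8)
        images.append(img8)
        if out_dir is not None:
            out = Path(out_dir)
            out.mkdir(parents=True, exist_ok=True)
            iio.imwrite(
                out / f"event_t{event.track_id}_f{f:06d}.png", img8
            )
    return images
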