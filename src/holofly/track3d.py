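"""3D trajectory post-processing.

Raw per-frame depth estimates are sparse (the focus quality gate leaves
gaps) and noisy (single-view holography has millimeter-scale depth
uncertainty versus sub-pixel transverse uncertainty).  This module converts
pixel tracks to metric coordinates, fills gaps by linear interpolation
between high-quality seeds, and replaces the jittery raw positions with the
integral of a sparsely sampled velocity: velocities are only measured
between sample pairs whose displacement exceeds the per-axis detection
uncertainty, so stationary segments collapse to their mean instead of
accumulating noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .optics import OpticsConfig
from .track2d import Track2D

__all__ = [
    "Track3D",
    "to_metric",
    "interpolate_gaps",
    "velocity_correct",
]

log = logging.getLogger(__name__)

SOURCE_MEASURED = "measured"
SOURCE_INTERPOLATED = "interpolated"
SOURCE_CORRECTED = "corrected"

#: default per-axis detection uncertainties: transverse 5% of a 3 mm body,
#: longitudinal from the depth-of-focus calibration on synthetic holograms
DEFAULT_XY_UNCERT_M = 0.15e-3
DEFAULT_Z_UNCERT_M = 2e-3


class TooFewSeedsError(ValueError):
    """Raised when a track has fewer than two measured depth samples."""


@dataclass
class Track3D:
    """Metric 3D trajectory of one object, frame by frame."""

    track_id: int
    frames: np.ndarray  # int frame indices, strictly increasing
    t_s: np.ndarray
    x_m: np.ndarray
    y_m: np.ndarray
    z_m: np.ndarray  # NaN where missing
    source: np.ndarray  # per-frame provenance flag
    speed_mm_s: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        for name in ("t_s", "x_m", "y_m", "z_m"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.source = np.asarray(self.source, dtype=object)
        if np.any(np.diff(self.t_s) <= 0):
            raise ValueError("time must be strictly increasing")

    @property
    def positions_m(self) -> np.ndarray:
        return np.column_stack([self.x_m, self.y_m, self.z_m])

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "track_id": self.track_id,
                "frame": self.frames,
                "t_s": self.t_s,
                "x_mm": self.x_m * 1e3,
                "y_mm": self.y_m * 1e3,
                "z_mm": self.z_m * 1e3,
                "source": self.source,
            }
        )
        if self.speed_mm_s is not None:
            df["speed_mm_s"] = self.speed_mm_s
        return df


def to_metric(
    track: Track2D,
    z_by_frame: dict[int, float | None],
    optics: OpticsConfig,
    fps: float = 100.0,
) -> Track3D:
    """Convert a pixel-space track plus depth estimates to metric 3D.

    ``x = col * pitch`` and ``y = row * pitch`` with the origin at the
    top-left of the hologram plane; ``z`` is the estimated depth from the
    sensor plane (NaN where the focus search left a gap).
    """
    frames = np.array(track.frames, dtype=int)
    pitch = optics.pixel_pitch_m
    rows = np.array([track.position(f)[0] for f in frames])
    cols = np.array([track.position(f)[1] for f in frames])
    z = np.array(
        [
            np.nan if z_by_frame.get(int(f)) is None else float(z_by_frame[int(f)])
            for f in frames
        ]
    )
    source = np.where(np.isnan(z), "missing", SOURCE_MEASURED).astype(object)
    return Track3D(
        track_id=track.track_id,
        frames=frames,
        t_s=frames / fps,
        x_m=cols * pitch,
        y_m=rows * pitch,
        z_m=z,
        source=source,
    )


def interpolate_gaps(track: Track3D) -> Track3D:
    """Fill missing depths linearly between measured seeds.

    Interior gaps are linearly interpolated in time between the flanking
    measured values; leading/trailing gaps take the nearest seed (constant
    extension).  Requires at least two measured samples, otherwise the
    track is not usable and :class:`TooFewSeedsError` is raised.
    """
    z = track.z_m.copy()
    seeds = ~np.isnan(z)
    if seeds.sum() < 2:
        raise TooFewSeedsError(
            f"track {track.track_id}: {int(seeds.sum())} depth seed(s)"
        )
    filled = np.interp(track.t_s, track.t_s[seeds], z[seeds])
    source = track.source.copy()
    source[~seeds] = SOURCE_INTERPOLATED
    return replace(track, z_m=filled, source=source)


def _segment_breaks(
    pos: np.ndarray, uncert: np.ndarray
) -> list[tuple[int, int, bool]]:
    """Split samples into (start, end, moving) spans by displacement gating.

    Scanning from an anchor, a span closes at the first sample whose
    displacement from the anchor exceeds the uncertainty on any axis
    (``moving=True``); a trailing span that never crosses is stationary.
    """
    n = pos.shape[0]
    spans = []
    i0 = 0
    while i0 < n - 1:
        j = i0 + 1
        moving = False
        while j < n:
            if np.any(np.abs(pos[j] - pos[i0]) > uncert):
                moving = True
                break
            j += 1
        if moving:
            spans.append((i0, j, True))
            i0 = j
        else:
            spans.append((i0, n - 1, False))
            break
    return spans


def velocity_correct(
    track: Track3D,
    xy_uncert_m: float = DEFAULT_XY_UNCERT_M,
    z_uncert_m: float = DEFAULT_Z_UNCERT_M,
) -> Track3D:
    """Replace positions by the integral of a sparsely sampled velocity.

    Velocity is estimated only across spans whose end-to-end displacement
    exceeds the per-axis uncertainty, then positions inside each span are
    laid out linearly between the measured span endpoints.  Spans that
    never cross the uncertainty (stationary flies) collapse to their mean
    position with zero speed.  The per-frame speed series (piecewise
    constant over spans, in mm/s) is attached.  The operation is
    idempotent: a corrected track is already piecewise linear, so a second
    pass reproduces it.
    """
    pos = track.positions_m
    if np.any(np.isnan(pos)):
        raise ValueError("velocity_correct requires a gap-filled track")
    uncert = np.array([xy_uncert_m, xy_uncert_m, z_uncert_m])
    n = pos.shape[0]
    # iterate to a fixed point: one sweep can shift span boundaries where a
    # stationary stretch meets motion, so sweeps repeat until the layout is
    # stable (which also makes the whole operation idempotent)
    corrected = pos.copy()
    speed = np.zeros(n)
    for _ in range(10):
        new_pos, speed = _correct_once(corrected, track.t_s, uncert)
        delta = np.abs(new_pos - corrected).max()
        corrected = new_pos
        if delta < 1e-12:
            break
    source = np.full(n, SOURCE_CORRECTED, dtype=object)
    return replace(
        track,
        x_m=corrected[:, 0],
        y_m=corrected[:, 1],
        z_m=corrected[:, 2],
        source=source,
        speed_mm_s=speed,
    )


def _correct_once(
    pos: np.ndarray, t_s: np.ndarray, uncert: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    n = pos.shape[0]
    corrected = pos.copy()
    speed = np.zeros(n)
    for i0, i1, moving in _segment_breaks(pos, uncert):
        if moving:
            dt = t_s[i1] - t_s[i0]
            v = (pos[i1] - pos[i0]) / dt
            frac = (t_s[i0 : i1 + 1] - t_s[i0])[:, None]
            corrected[i0 : i1 + 1] = pos[i0] + v[None, :] * frac
            speed[i0 : i1 + 1] = np.linalg.norm(v) * 1e3
        else:
            corrected[i0 : i1 + 1] = pos[i0 : i1 + 1].mean(axis=0)
            speed[i0 : i1 + 1] = 0.0
    return corrected, speed
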