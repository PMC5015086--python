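"""Hologram enhancement and 2D segmentation.

The raw frames contain static background structure (window aberrations,
illumination shading) on top of the fly diffraction patterns.  The cleanup
chain is: subtract a time-averaged background, smooth with a moving-average
filter so the partially transparent wings do not fragment the body on
thresholding, threshold automatically at the midpoint between the first two
histogram peaks (flies are darker than the background), open with a disk
matched to the appendage width so legs and wings do not bias the centroid,
and label the remaining components.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage, signal
from skimage import measure
from skimage.filters import threshold_otsu

from .frames import HologramFrame

__all__ = [
    "BackgroundModel",
    "Detection2D",
    "estimate_background",
    "enhance",
    "auto_threshold",
    "segment",
    "disk_footprint",
]

log = logging.getLogger(__name__)

#: default minimum component area: 25% of the nominal body ellipse
#: (3 mm body, axis ratio 0.4, 30 um/px -> pi * 50 * 20 px^2)
DEFAULT_MIN_AREA_PX = int(0.25 * np.pi * 50 * 20)


@dataclass
class BackgroundModel:
    """Pixelwise time-averaged background."""

    mean_frame: np.ndarray
    n_frames_used: int


@dataclass
class Detection2D:
    """One segmented object in one frame."""

    frame_index: int
    centroid_px: tuple[float, float]  # (row, col), sub-pixel
    area_px: int
    bbox: tuple[int, int, int, int]  # (row0, col0, row1, col1), half-open

    def __post_init__(self) -> None:
        r, c = self.centroid_px
        r0, c0, r1, c1 = self.bbox
        if not (r0 <= r <= r1 and c0 <= c <= c1):
            raise ValueError("bbox must contain the centroid")


def estimate_background(
    frames: Iterable[HologramFrame | np.ndarray],
) -> BackgroundModel:
    """Pixelwise arithmetic mean over frames (streaming, constant memory)."""
    total = None
    n = 0
    for frame in frames:
        pixels = frame.pixels if isinstance(frame, HologramFrame) else frame
        pixels = np.asarray(pixels, dtype=np.float64)
        if total is None:
            total = pixels.copy()
        else:
            if pixels.shape != total.shape:
                raise ValueError("all frames must share one shape")
            total += pixels
        n += 1
    if n == 0:
        raise ValueError("cannot estimate a background from zero frames")
    return BackgroundModel(mean_frame=total / n, n_frames_used=n)


class StreamingBackground:
    """Incremental version of :func:`estimate_background` for pipelines."""

    def __init__(self) -> None:
        self._total: np.ndarray | None = None
        self._n = 0

    def update(self, frame: HologramFrame | np.ndarray) -> None:
        pixels = frame.pixels if isinstance(frame, HologramFrame) else frame
        pixels = np.asarray(pixels, dtype=np.float64)
        if self._total is None:
            self._total = pixels.copy()
        else:
            self._total += pixels
        self._n += 1

    def finalize(self) -> BackgroundModel:
        if self._n == 0:
            raise ValueError("no frames accumulated")
        return BackgroundModel(self._total / self._n, self._n)


def enhance(
    frame: HologramFrame | np.ndarray,
    bg: BackgroundModel,
    smooth_window: int = 5,
) -> np.ndarray:
    """Background-subtract, shift to a nonnegative range, and box-filter.

    Flies come out *darker* than the (flat) residual background, matching
    the below-threshold-is-foreground rule used by :func:`segment`.
    """
    pixels = frame.pixels if isinstance(frame, HologramFrame) else frame
    pixels = np.asarray(pixels, dtype=np.float64)
    if pixels.shape != bg.mean_frame.shape:
        raise ValueError("frame and background shapes differ")
    if smooth_window < 1 or smooth_window >= min(pixels.shape):
        raise ValueError("smooth_window must be in [1, min(frame shape))")
    diff = pixels - bg.mean_frame
    diff -= diff.min()
    if smooth_window > 1:
        diff = ndimage.uniform_filter(
            diff, size=smooth_window, mode="constant", cval=0.0
        )
    return diff


def auto_threshold(
    image: np.ndarray,
    n_bins: int = 256,
    smooth_bins: int = 5,
    min_separation_bins: int = 10,
    valley_max_frac: float = 0.2,
) -> float:
    """Midpoint between the first two peaks of the intensity histogram.

    The histogram is smoothed with a moving average before peak finding to
    suppress spurious maxima; peaks closer together than
    ``min_separation_bins`` are merged.  Two maxima only count as separate
    modes if the valley between them drops below ``valley_max_frac`` of the
    smaller peak — the wiggles of a unimodal histogram never do.  The first
    qualifying pair in ascending intensity defines the threshold (dark fly
    mode vs. bright background mode); if none exists the function falls
    back to an Otsu split with a warning.  Pixels *below* the returned
    threshold are candidate fly/noise pixels.
    """
    image = np.asarray(image, dtype=np.float64)
    lo, hi = float(image.min()), float(image.max())
    if hi <= lo:
        raise ValueError("cannot threshold a constant image")
    counts, edges = np.histogram(image, bins=n_bins, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    smoothed = ndimage.uniform_filter1d(
        counts.astype(float), size=smooth_bins, mode="nearest"
    )
    # prominence floor keeps single-pixel wiggles from counting as modes
    prominence = max(1.0, 1e-4 * image.size)
    peaks, _ = signal.find_peaks(
        smoothed, distance=min_separation_bins, prominence=prominence
    )
    peaks = sorted(peaks)
    for a in range(len(peaks)):
        for b in range(a + 1, len(peaks)):
            i, j = peaks[a], peaks[b]
            valley = smoothed[i : j + 1].min()
            if valley <= valley_max_frac * min(smoothed[i], smoothed[j]):
                return float(0.5 * (centers[i] + centers[j]))
    warnings.warn(
        "no bimodal histogram structure found; falling back to Otsu",
        stacklevel=2,
    )
    return float(threshold_otsu(image, nbins=n_bins))


def disk_footprint(diameter_px: float) -> np.ndarray:
    """Binary disk structuring element of the given *diameter* in pixels."""
    if diameter_px < 1:
        raise ValueError("diameter_px must be >= 1")
    n = int(np.ceil(diameter_px))
    c = (n - 1) / 2.0
    rr = np.arange(n)[:, None] - c
    cc = np.arange(n)[None, :] - c
    return (rr * rr + cc * cc) <= (diameter_px / 2.0) ** 2


def segment(
    image: np.ndarray,
    threshold: float,
    opening_diameter_px: float = 10.0,
    min_area_px: int = DEFAULT_MIN_AREA_PX,
    frame_index: int = 0,
    weighted_centroids: bool = True,
) -> list[Detection2D]:
    """Binarize, open, label, and measure fly candidates.

    Foreground is everything *below* the threshold.  The binary opening
    removes structures thinner than the disk (legs, wings); components
    smaller than ``min_area_px`` are discarded as noise.  Centroids are
    intensity-weighted on the inverted enhanced image by default (plain
    binary centroids with ``weighted_centroids=False``).
    """
    image = np.asarray(image, dtype=np.float64)
    mask = image < threshold
    if opening_diameter_px >= 2:
        mask = ndimage.binary_opening(
            mask, structure=disk_footprint(opening_diameter_px)
        )
    labels, _ = ndimage.label(mask)
    weight = image.max() - image  # bright inside the fly
    detections: list[Detection2D] = []
    for region in measure.regionprops(labels, intensity_image=weight):
        if region.area < min_area_px:
            continue
        centroid = (
            region.centroid_weighted if weighted_centroids else region.centroid
        )
        r0, c0, r1, c1 = region.bbox
        detections.append(
            Detection2D(
                frame_index=frame_index,
                centroid_px=(float(centroid[0]), float(centroid[1])),
                area_px=int(region.area),
                bbox=(int(r0), int(c0), int(r1), int(c1)),
            )
        )
    return detections
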