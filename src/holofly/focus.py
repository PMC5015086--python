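"""Depth-from-focus for tracked objects.

For each detected fly the enhanced hologram is cropped around the centroid,
apodized, and Fourier transformed once; the spectrum is then multiplied by
the (unit-modulus) Fresnel kernel for every depth on the search grid and
inverse-transformed, and the l1 norm of the reconstructed amplitude is
recorded as a 1D focus-metric curve F(z).  Only that curve is kept — never
the 3D reconstruction stack — which is what makes depth search tractable
over long recordings.

For an opaque silhouette the background-subtracted hologram is a sparse
object convolved with a diffraction kernel: refocusing concentrates its
amplitude onto the compact silhouette.  Since the kernel preserves the l2
norm exactly, concentration *minimizes* the l1 norm, so the in-focus plane
is the sharp extremum of F(z).  The extremum sense is configurable; the
package default (``"minimize"``) is the sense that recovers ground-truth
depth on synthetic holograms (see docs/methods.md).

Sub-grid resolution comes from a cubic-spline fit around the sampled
extremum, and a multi-pass quality gate (prominence over the curve's median
absolute deviation) leaves ambiguous frames as gaps for the trajectory
post-processing to fill.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import fft as _fft
from scipy import signal
from scipy.interpolate import CubicSpline

from .optics import OpticsConfig, fresnel_kernel

__all__ = [
    "FocusConfig",
    "FocusCurve",
    "prepare_crop",
    "focus_metric_curve",
    "variance_metric_curve",
    "refine_peak",
    "multipass_select",
    "estimate_depth",
]


@dataclass(frozen=True)
class FocusConfig:
    """Parameters of the focus-metric computation.

    ``lpf_sigma_frac`` is the width of the frequency-domain Gaussian
    low-pass filter as a fraction of the Nyquist frequency (it suppresses
    sensor noise before the l1 norm); ``quality_min`` is the minimum peak
    prominence in units of the curve's median absolute deviation.
    """

    crop_px: int = 150
    pad_px: int = 256
    tukey_alpha: float = 0.5
    lpf_sigma_frac: float = 0.5
    quality_min: float = 35.0
    sense: str = "minimize"
    spline_halfwidth: int = 5
    support_px: int | None = None

    def __post_init__(self) -> None:
        if self.pad_px < self.crop_px:
            raise ValueError("pad_px must be >= crop_px")
        if self.quality_min < 0:
            raise ValueError("quality_min must be nonnegative")
        if self.sense not in ("minimize", "maximize"):
            raise ValueError("sense must be 'minimize' or 'maximize'")

    @property
    def metric_support_px(self) -> int:
        """Side of the central region the metric is summed over.

        The reconstruction is evaluated only over the original crop support
        (plus a small margin): the zero-padded border contains nothing but
        the spreading defocus halo, whose monotone growth with z would tilt
        the focus curve and bias the extremum.
        """
        if self.support_px is not None:
            return min(self.support_px, self.pad_px)
        return min(self.crop_px + 10, self.pad_px)


@dataclass
class FocusCurve:
    """Sampled focus metric F(z) with detected extrema."""

    z_samples_m: np.ndarray
    metric_values: np.ndarray
    sense: str = "minimize"
    peaks: list[tuple[float, float]] = field(default_factory=list)
    selected_z_m: float | None = None

    def __post_init__(self) -> None:
        self.z_samples_m = np.asarray(self.z_samples_m, dtype=float)
        self.metric_values = np.asarray(self.metric_values, dtype=float)
        if self.z_samples_m.shape != self.metric_values.shape:
            raise ValueError("z grid and metric values must align")
        if not np.all(np.isfinite(self.metric_values)):
            raise ValueError("metric values must be finite")

    def signed(self) -> np.ndarray:
        """Metric with the wanted extremum mapped to a maximum."""
        return (
            self.metric_values
            if self.sense == "maximize"
            else -self.metric_values
        )


def prepare_crop(
    enhanced_frame: np.ndarray,
    center_px: tuple[float, float],
    cfg: FocusConfig,
) -> np.ndarray:
    """Crop, zero-mean, Tukey-window, zero-pad, and Fourier transform.

    The crop is ``crop_px`` square around ``center_px``; regions outside
    the frame are zero-filled (the crop is never shifted, so the object
    stays registered to the crop center).  The crop mean is removed before
    windowing so the padded borders introduce no step, then the spectrum of
    the ``pad_px``-square grid is returned.
    """
    frame = np.asarray(enhanced_frame, dtype=np.float64)
    n = cfg.crop_px
    r0 = int(round(center_px[0])) - n // 2
    c0 = int(round(center_px[1])) - n // 2
    crop = np.zeros((n, n))
    rs0, rs1 = max(r0, 0), min(r0 + n, frame.shape[0])
    cs0, cs1 = max(c0, 0), min(c0 + n, frame.shape[1])
    if rs0 < rs1 and cs0 < cs1:
        crop[rs0 - r0 : rs1 - r0, cs0 - c0 : cs1 - c0] = frame[rs0:rs1, cs0:cs1]
        valid = (rs1 - rs0) * (cs1 - cs0)
        crop[rs0 - r0 : rs1 - r0, cs0 - c0 : cs1 - c0] -= (
            crop[rs0 - r0 : rs1 - r0, cs0 - c0 : cs1 - c0].sum() / valid
        )
    win = signal.windows.tukey(n, alpha=cfg.tukey_alpha)
    crop *= win[:, None] * win[None, :]
    padded = np.zeros((cfg.pad_px, cfg.pad_px))
    off = (cfg.pad_px - n) // 2
    padded[off : off + n, off : off + n] = crop
    return _fft.fft2(padded)


def _gaussian_lpf(pad_px: int, pitch_m: float, sigma_frac: float) -> np.ndarray:
    f = _fft.fftfreq(pad_px, d=pitch_m)
    f2 = f[:, None] ** 2 + f[None, :] ** 2
    sigma = sigma_frac * 0.5 / pitch_m  # fraction of Nyquist
    return np.exp(-f2 / (2.0 * sigma**2))


def focus_metric_curve(
    spectrum: np.ndarray,
    cfg: FocusConfig,
    optics: OpticsConfig,
    z_grid_m: np.ndarray | None = None,
) -> FocusCurve:
    """l1 focus metric over the depth grid.

    The Gaussian low-pass is applied once (it is z-independent); each depth
    costs one kernel multiply and one inverse transform, and only the
    scalar l1 norm of the reconstructed amplitude is stored.
    """
    z_grid = optics.z_grid_m if z_grid_m is None else np.asarray(z_grid_m)
    if z_grid.size == 0:
        raise ValueError("empty z grid")
    spec = spectrum * _gaussian_lpf(
        spectrum.shape[0], optics.pixel_pitch_m, cfg.lpf_sigma_frac
    )
    region = _support_slice(spec.shape[0], cfg.metric_support_px)
    values = np.empty(z_grid.size)
    for i, z in enumerate(z_grid):
        kernel = fresnel_kernel(
            spec.shape, optics.pixel_pitch_m, optics.wavelength_m, -z
        )
        field = _fft.ifft2(spec * kernel)
        values[i] = np.abs(field[region]).sum()
    return FocusCurve(z_grid, values, sense=cfg.sense)


def _support_slice(pad_px: int, support_px: int) -> tuple[slice, slice]:
    s0 = (pad_px - support_px) // 2
    s = slice(s0, s0 + support_px)
    return (s, s)


def variance_metric_curve(
    spectrum: np.ndarray,
    optics: OpticsConfig,
    z_grid_m: np.ndarray | None = None,
    support_px: int = 160,
) -> FocusCurve:
    """Reference variance focus metric over full reconstructions (maximize).

    Classic reconstruction-stack criterion: the variance of the
    reconstructed image (amplitude, over the crop support) peaks in the
    in-focus plane.  It shares nothing with the l1 statistic and is used
    as an independent cross-check of the depth search; the stack is still
    processed one plane at a time.
    """
    z_grid = optics.z_grid_m if z_grid_m is None else np.asarray(z_grid_m)
    region = _support_slice(spectrum.shape[0], min(support_px, spectrum.shape[0]))
    values = np.empty(z_grid.size)
    for i, z in enumerate(z_grid):
        kernel = fresnel_kernel(
            spectrum.shape, optics.pixel_pitch_m, optics.wavelength_m, -z
        )
        field = _fft.ifft2(spectrum * kernel)
        values[i] = np.var(np.abs(field[region]))
    return FocusCurve(z_grid, values, sense="maximize")


def refine_peak(
    curve: FocusCurve, peak_index: int
) -> tuple[float, bool]:
    """Sub-grid extremum location from a cubic-spline fit.

    Fits a spline through the samples within ``spline_halfwidth`` grid
    steps of the sampled extremum and evaluates it densely (grid step /
    100).  Returns ``(z_refined, at_boundary)``; the refined position never
    moves more than one grid step from the sample, and extrema at the grid
    boundary are returned as-is with the boundary flag raised.
    """
    z = curve.z_samples_m
    s = curve.signed()
    n = z.size
    if peak_index in (0, n - 1):
        return float(z[peak_index]), True
    lo = max(0, peak_index - 5)
    hi = min(n, peak_index + 6)
    spline = CubicSpline(z[lo:hi], s[lo:hi])
    step = z[1] - z[0] if n > 1 else 0.0
    dense = np.arange(
        max(z[lo], z[peak_index] - step),
        min(z[hi - 1], z[peak_index] + step) + step / 200.0,
        step / 100.0,
    )
    refined = float(dense[np.argmax(spline(dense))])
    return refined, False


def _find_extrema(curve: FocusCurve) -> tuple[np.ndarray, np.ndarray]:
    """Indices of candidate extrema and their quality scores.

    Quality is the peak prominence divided by a robust estimate of the
    curve's point-to-point noise (from the median absolute second
    difference): a genuine focus dip rises orders of magnitude above the
    wiggles of an empty or pure-noise crop.
    """
    s = curve.signed()
    idx, props = signal.find_peaks(s, prominence=0.0)
    if idx.size == 0:
        return idx, np.empty(0)
    d2 = np.diff(curve.metric_values, 2)
    sigma = 1.4826 * np.median(np.abs(d2 - np.median(d2))) / np.sqrt(6.0)
    scale = sigma if sigma > 0 else max(np.ptp(curve.metric_values) * 1e-6, 1e-30)
    quality = props["prominences"] / scale
    return idx, quality


def multipass_select(
    curve: FocusCurve,
    cfg: FocusConfig,
    prior_z_m: float | None = None,
) -> FocusCurve:
    """Quality-gated peak selection; ambiguous frames become gaps.

    Pass 1 keeps only extrema with quality (prominence / curve MAD) at or
    above ``quality_min``.  A unique survivor is selected; with several
    survivors and a prior depth (e.g. the previous frame of the same
    track), the one nearest the prior wins; otherwise the frame is left as
    a gap for trajectory post-processing.  The curve is annotated and
    returned.
    """
    idx, quality = _find_extrema(curve)
    peaks: list[tuple[float, float]] = []
    for i, q in zip(idx, quality):
        z_ref, _ = refine_peak(curve, int(i))
        peaks.append((z_ref, float(q)))
    curve.peaks = peaks
    qualifying = [(z, q) for z, q in peaks if q >= cfg.quality_min]
    if len(qualifying) == 1:
        curve.selected_z_m = qualifying[0][0]
    elif len(qualifying) > 1 and prior_z_m is not None:
        curve.selected_z_m = min(
            qualifying, key=lambda p: abs(p[0] - prior_z_m)
        )[0]
    else:
        curve.selected_z_m = None
    return curve


def estimate_depth(
    enhanced_frame: np.ndarray,
    center_px: tuple[float, float],
    cfg: FocusConfig,
    optics: OpticsConfig,
    prior_z_m: float | None = None,
) -> FocusCurve:
    """Full per-detection depth estimate: crop -> curve -> selection."""
    spectrum = prepare_crop(enhanced_frame, center_px, cfg)
    curve = focus_metric_curve(spectrum, cfg, optics)
    return multipass_select(curve, cfg, prior_z_m=prior_z_m)
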