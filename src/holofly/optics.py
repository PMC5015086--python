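"""Paraxial (Fresnel) free-space propagation of sampled optical fields.

Inline holography encodes depth in interference fringes: a collimated beam
passes through the arena, each fly blocks part of the wavefront, and the
sensor records the intensity of the diffracted field.  Both the forward
simulation and the numerical refocusing used for depth estimation share a
single primitive: multiplying the field's spectrum by the Fresnel transfer
function

    H(fx, fy; z) = exp(i 2*pi*z/lambda) * exp(-i*pi*lambda*z*(fx^2 + fy^2))

which propagates a monochromatic field a distance ``z`` under the paraxial
(small-angle) approximation.  The approximation is valid here because the
arena sits far from the sensor relative to its transverse size.

Sign convention (fixed package-wide): ``propagate(field, z)`` with ``z > 0``
carries the field *from an object plane toward the sensor* over distance
``z``.  Refocusing a hologram recorded with the object at depth ``z``
therefore uses ``propagate(hologram, -z)``; since ``H(-z) == conj(H(z))``
this is identical to applying the conjugate ("backward") kernel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import fft as _fft

__all__ = [
    "OpticsConfig",
    "ComplexField",
    "fresnel_kernel",
    "propagate",
]


@dataclass(frozen=True)
class OpticsConfig:
    """Geometry and illumination of the holographic recording.

    Parameters
    ----------
    wavelength_m
        Illumination wavelength (He-Ne laser, 633 nm).
    pixel_pitch_m
        Effective pixel pitch at object scale (30 um/pixel).
    sensor_shape
        ``(rows, cols)`` of the sensor grid.
    z_min_m, z_max_m, z_step_m
        Longitudinal search grid for depth estimation, measured from the
        sensor plane.
    """

    wavelength_m: float = 633e-9
    pixel_pitch_m: float = 30e-6
    sensor_shape: tuple[int, int] = (1024, 2048)
    z_min_m: float = 0.135
    z_max_m: float = 0.200
    z_step_m: float = 0.001

    def __post_init__(self) -> None:
        if self.wavelength_m <= 0:
            raise ValueError("wavelength_m must be positive")
        if self.pixel_pitch_m <= 0:
            raise ValueError("pixel_pitch_m must be positive")
        if len(self.sensor_shape) != 2 or min(self.sensor_shape) < 1:
            raise ValueError("sensor_shape must be two positive integers")
        if not self.z_min_m < self.z_max_m:
            raise ValueError("z_min_m must be smaller than z_max_m")
        if self.z_step_m <= 0:
            raise ValueError("z_step_m must be positive")

    @property
    def z_grid_m(self) -> np.ndarray:
        """Depth search grid, inclusive of both ends (up to rounding)."""
        n = int(round((self.z_max_m - self.z_min_m) / self.z_step_m))
        return self.z_min_m + self.z_step_m * np.arange(n + 1)

    @property
    def fov_m(self) -> tuple[float, float]:
        """Transverse field of view ``(height, width)`` in meters."""
        r, c = self.sensor_shape
        return (r * self.pixel_pitch_m, c * self.pixel_pitch_m)

    @property
    def paraxial_ok(self) -> bool:
        """Whether the nearest search depth satisfies the small-angle regime.

        A conservative check: the propagation distance should be at least
        twice the largest transverse extent of the field of view.
        """
        return self.z_min_m >= 2.0 * max(self.fov_m)


@dataclass
class ComplexField:
    """A sampled complex optical field with its transverse sample pitch."""

    values: np.ndarray
    pitch_m: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.complex128)
        if self.values.ndim != 2:
            raise ValueError("field values must be a 2D grid")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("field values must be finite")
        if self.pitch_m <= 0:
            raise ValueError("pitch_m must be positive")

    @property
    def intensity(self) -> np.ndarray:
        return np.abs(self.values) ** 2


def fresnel_kernel(
    shape: tuple[int, int],
    pitch_m: float,
    wavelength_m: float,
    z_m: float,
) -> np.ndarray:
    """Fresnel transfer function on the discrete FFT frequency grid.

    Returns a unit-modulus complex grid with the DC sample at index (0, 0),
    matching numpy's FFT layout.  ``fresnel_kernel(..., -z)`` is the complex
    conjugate of ``fresnel_kernel(..., z)``, so forward and backward
    propagation are exact inverses.
    """
    rows, cols = shape
    if rows < 1 or cols < 1:
        raise ValueError("shape must be positive")
    if pitch_m <= 0 or wavelength_m <= 0:
        raise ValueError("pitch and wavelength must be positive")
    fy = _fft.fftfreq(rows, d=pitch_m)[:, None]
    fx = _fft.fftfreq(cols, d=pitch_m)[None, :]
    phase = 2.0 * np.pi * z_m / wavelength_m - np.pi * wavelength_m * z_m * (
        fx * fx + fy * fy
    )
    return np.exp(1j * phase)


def _kernel_stack(
    shape: tuple[int, int],
    pitch_m: float,
    wavelength_m: float,
    z_values_m: np.ndarray,
) -> np.ndarray:
    """Fresnel kernels for many depths, stacked along axis 0."""
    rows, cols = shape
    fy = _fft.fftfreq(rows, d=pitch_m)[:, None]
    fx = _fft.fftfreq(cols, d=pitch_m)[None, :]
    f2 = fx * fx + fy * fy
    z = np.asarray(z_values_m, dtype=float)[:, None, None]
    phase = 2.0 * np.pi * z / wavelength_m - np.pi * wavelength_m * z * f2
    return np.exp(1j * phase)


def propagate(
    field: ComplexField | np.ndarray,
    cfg: OpticsConfig,
    z_m: float,
) -> ComplexField:
    """Propagate a field by a signed distance using the Fresnel kernel.

    Positive ``z_m`` moves the field toward the sensor; a hologram recorded
    with the object at depth ``z`` is refocused with ``-z``.  Energy (the
    squared l2 norm) is conserved exactly because the kernel has unit
    modulus.
    """
    if isinstance(field, ComplexField):
        values = field.values
        pitch = field.pitch_m
    else:
        values = np.asarray(field, dtype=np.complex128)
        pitch = cfg.pixel_pitch_m
    kernel = fresnel_kernel(values.shape, pitch, cfg.wavelength_m, z_m)
    out = _fft.ifft2(_fft.fft2(values) * kernel)
    return ComplexField(out, pitch)
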