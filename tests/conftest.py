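"""Shared fixtures: small-sensor optics and reusable synthetic frames."""

import numpy as np
import pytest

from holofly.optics import OpticsConfig
from holofly.preprocess import BackgroundModel
from holofly.synth import SyntheticFly, simulate_hologram

SENSOR = 512
PITCH = 30e-6


@pytest.fixture(scope="session")
def optics512() -> OpticsConfig:
    """Square test sensor; same pitch/wavelength/z-grid as the full system."""
    return OpticsConfig(sensor_shape=(SENSOR, SENSOR))


@pytest.fixture(scope="session")
def flat_background(optics512) -> BackgroundModel:
    """Ideal fly-free background at the default illumination level."""
    empty = simulate_hologram([], optics512, noise_sd=0.0)
    return BackgroundModel(empty.pixels, 1)


@pytest.fixture(scope="session")
def single_fly_frame(optics512):
    """Factory: one fly at (row, col, z) px/m -> (frame, fly)."""

    def make(row_px=255.5, col_px=255.5, z_m=0.160, noise_sd=0.01, seed=0,
             orientation=0.0, **fly_kwargs):
        fly = SyntheticFly(
            position_m=(col_px * PITCH, row_px * PITCH, z_m),
            orientation_rad=orientation,
            **fly_kwargs,
        )
        frame = simulate_hologram(
            [fly], optics512, noise_sd=noise_sd, seed=seed
        )
        return frame, fly

    return make
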