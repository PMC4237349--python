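import numpy as np
import pytest

from dragtag.drag import FluidEnv
from dragtag.kinematics import LandmarkTrack
from dragtag.respirometry import MetabolicModel, MO2Sample


@pytest.fixture
def env() -> FluidEnv:
    """Seawater environment at the experimental reference speed."""
    return FluidEnv(density=1020.0, drag_coefficient=0.45, reference_speed=0.65)


@pytest.fixture
def control_model() -> MetabolicModel:
    """Control-group metabolic curve: SMR 40.58, U_opt 0.68 (c = 1/0.68)."""
    return MetabolicModel(smr=40.58, c=1.4706, fit_r2=1.0)


@pytest.fixture
def exact_mo2_samples(control_model):
    """Noise-free MO2 samples on the control curve at 0.3-0.9 m/s."""
    speeds = np.round(np.arange(0.3, 0.95, 0.1), 10)
    return [
        MO2Sample(
            speed=float(u),
            mo2=control_model.smr * np.exp(control_model.c * u),
            r2=1.0,
            p_value=1e-9,
        )
        for u in speeds
    ]


@pytest.fixture
def sine_track():
    """Factory for sinusoidal landmark tracks sampled at 30 Hz."""

    def make(
        freq: float,
        half_amp: float = 0.038,
        duration: float = 20.0,
        phase: float = 0.0,
        offset: float = 0.0,
        noise_sd: float = 0.0,
        seed: int = 0,
        speed: float = 0.65,
        site: str = "tail",
    ) -> LandmarkTrack:
        t = np.arange(0.0, duration, 1.0 / 30.0)
        y = half_amp * np.sin(2.0 * np.pi * freq * t + phase) + offset
        if noise_sd > 0:
            y = y + np.random.default_rng(seed).normal(0.0, noise_sd, t.size)
        return LandmarkTrack(t, y, 30.0, speed, site)

    return make
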