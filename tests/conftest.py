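"""Shared fixtures: acquisition settings and pre-rendered phantom stacks."""

from __future__ import annotations

import pytest

from vchopper import (
    AcquisitionConfig,
    NoiseModel,
    render_phantom_video,
    three_region_phantom,
    two_shape_phantom,
)

# microsecond-imaging settings: 50 Hz pulses / 40% duty, 30 fps (actual
# 29.98), 1/350 s exposure — the two-shape phantom acquisition
MICRO_CONFIG = AcquisitionConfig(
    pulse_frequency_hz=50.0,
    duty_cycle=0.4,
    nominal_frame_rate_fps=30.0,
    frame_rate_drift_fps=0.02,
    drift_sign=-1,
    shutter_s=1.0 / 350.0,
)

# sub-hundred-microsecond settings: 30 Hz pulses, 30 fps, 1/500 s exposure
SUBHUNDRED_CONFIG = AcquisitionConfig(
    pulse_frequency_hz=30.0,
    duty_cycle=0.4,
    nominal_frame_rate_fps=30.0,
    frame_rate_drift_fps=0.02,
    drift_sign=-1,
    shutter_s=1.0 / 500.0,
)

TWO_SHAPE_LIFETIMES = (168.4e-6, 512.3e-6)
THREE_REGION_LIFETIMES = (510.4e-6, 169.3e-6, 78.3e-6)


@pytest.fixture(scope="session")
def micro_config() -> AcquisitionConfig:
    return MICRO_CONFIG


@pytest.fixture(scope="session")
def subhundred_config() -> AcquisitionConfig:
    return SUBHUNDRED_CONFIG


@pytest.fixture(scope="session")
def two_shape_clean(micro_config):
    """Noise-free 16-bit two-shape phantom video, one full sweep."""
    spec = two_shape_phantom(
        shape=(48, 48), lifetimes_s=TWO_SHAPE_LIFETIMES, noise=None,
        bit_depth=16, rng_seed=11,
    )
    return spec, render_phantom_video(spec, micro_config, 19.0)


@pytest.fixture(scope="session")
def two_shape_noisy(micro_config):
    """Default-noise 8-bit two-shape phantom video, three sweeps."""
    spec = two_shape_phantom(
        shape=(48, 48), lifetimes_s=TWO_SHAPE_LIFETIMES, noise=NoiseModel(),
        bit_depth=8, rng_seed=12,
    )
    return spec, render_phantom_video(spec, micro_config, 55.0)


@pytest.fixture(scope="session")
def three_region_clean(subhundred_config):
    """Noise-free 16-bit three-region phantom video, one full sweep."""
    spec = three_region_phantom(
        shape=(48, 48), lifetimes_s=THREE_REGION_LIFETIMES, noise=None,
        bit_depth=16, rng_seed=13,
    )
    return spec, render_phantom_video(spec, subhundred_config, 31.0)


@pytest.fixture(scope="session")
def three_region_noisy(subhundred_config):
    """Default-noise 8-bit three-region phantom video, two sweeps."""
    spec = three_region_phantom(
        shape=(48, 48), lifetimes_s=THREE_REGION_LIFETIMES, noise=NoiseModel(),
        bit_depth=8, rng_seed=14,
    )
    return spec, render_phantom_video(spec, subhundred_config, 65.0)
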