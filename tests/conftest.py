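import numpy as np
import pytest

from synaptiq import ChannelSim, SegmentationParams, SimImageConfig


@pytest.fixture
def small_stack_cfg():
    """A fast, low-count two-channel confocal stack configuration."""
    return SimImageConfig(
        field_size_um=10.0,
        channels={
            "pre": ChannelSim(2.0e8),
            "post": ChannelSim(2.0e8),
        },
        colocalization_fraction=0.8,
        seed=11,
    )


@pytest.fixture
def clean_ribbon_cfg():
    """Noise-free array-tomography ribbon with sparse puncta and flickers."""
    return SimImageConfig(
        field_size_um=15.0,
        pixel_size_um=0.0587,
        n_sections=30,
        channels={
            "pre": ChannelSim(3.0e7, punctum_radius_um=0.15),
            "post": ChannelSim(3.0e7, punctum_radius_um=0.15),
        },
        colocalization_fraction=0.8,
        background_level=10.0,
        gaussian_noise_sd=0.0,
        poisson_noise=False,
        seed=5,
    )


@pytest.fixture
def default_params():
    return SegmentationParams()
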