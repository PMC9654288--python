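import warnings

import numpy as np
import pytest

from holoclass import (
    OpticalParams,
    SimulationConfig,
    generate_dataset,
)

# particle-outside-crop warnings are expected occasionally for large clusters
warnings.filterwarnings("ignore", message="particle at .* outside the crop")


@pytest.fixture
def optics() -> OpticalParams:
    return OpticalParams(wavelength_um=0.532, pixel_pitch_um=1.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_dataset():
    """A tiny but realistic 4-class dataset shared across tests (64x64 crops)."""
    cfg = SimulationConfig(
        crop_px=64,
        class_counts={"TRC1": 8, "TRC2": 8, "TRC4": 8, "SP": 8},
    )
    manifest, samples = generate_dataset(cfg, master_seed=7)
    return cfg, manifest, samples


@pytest.fixture(scope="session")
def balanced_100_manifest():
    """100-sample manifest (4 x 25) for split-protocol checks."""
    cfg = SimulationConfig(
        crop_px=64,
        class_counts={"TRC1": 25, "TRC2": 25, "TRC4": 25, "SP": 25},
        noise_sigma=0.0,
    )
    manifest, samples = generate_dataset(cfg, master_seed=11)
    return manifest, samples
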