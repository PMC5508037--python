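import numpy as np
import pytest

from rcaspot.synthetic import RegionSpec, SimConfig, simulate_tissue


def small_config(seed: int = 0, **overrides) -> SimConfig:
    """A desk-size two-area + control simulation used across the suite.

    Density 8e-4/px^2 over 256x256 regions gives ~50 informative spots per
    region; amplitude 10x background keeps detection easy.
    """
    base = dict(
        image_shape=(256, 768),
        n_z=2,
        regions=[
            RegionSpec(region_id=1, bbox=(0, 0, 256, 256), tumor_content=0.9,
                       density=8e-4, mutant_fraction=0.1),
            RegionSpec(region_id=2, bbox=(0, 256, 256, 256), tumor_content=0.9,
                       density=8e-4, mutant_fraction=0.4),
            RegionSpec(region_id=3, bbox=(0, 512, 256, 256), tumor_content=0.9,
                       density=8e-4, mutant_fraction=0.0),
        ],
        subclone=None,
        unspecific_rate=0.05,
        nuclei_density=2e-5,
        seed=seed,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def small_sim():
    """One simulated acquisition shared by read-only tests."""
    cfg = small_config(seed=11)
    channels, truth = simulate_tissue(cfg, control_region=3)
    return cfg, channels, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
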