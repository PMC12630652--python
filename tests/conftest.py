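import pytest

from cafomap import LandscapeConfig, generate_landscape


@pytest.fixture(scope="session")
def quiet_landscape():
    """A small zero-noise landscape: every pipeline stage should recover
    ground truth exactly on it."""
    cfg = LandscapeConfig(
        n_facilities=8,
        region_width_m=12_000,
        region_height_m=12_000,
        facility_separation_min_m=2_500,
        seed=42,
    ).zero_noise()
    return generate_landscape(cfg)


@pytest.fixture(scope="session")
def noisy_landscape():
    """A landscape with default (real-register-like) noise rates."""
    cfg = LandscapeConfig(
        n_facilities=10,
        region_width_m=14_000,
        region_height_m=14_000,
        seed=7,
    )
    return generate_landscape(cfg)
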