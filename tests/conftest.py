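import numpy as np
import pytest

from dropmorph.config import SyntheticConfig, large_droplet_config, small_droplet_config


def digital_disk(radius_px: int, pad: int = 5) -> np.ndarray:
    n = 2 * radius_px + 2 * pad + 1
    yy, xx = np.mgrid[:n, :n]
    c = n // 2
    return (yy - c) ** 2 + (xx - c) ** 2 <= radius_px**2


def digital_ellipse(semi_a_px: float, semi_b_px: float, pad: int = 5) -> np.ndarray:
    n = int(2 * max(semi_a_px, semi_b_px)) + 2 * pad + 1
    yy, xx = np.mgrid[:n, :n]
    c = n // 2
    return ((xx - c) / semi_a_px) ** 2 + ((yy - c) / semi_b_px) ** 2 <= 1.0


@pytest.fixture
def disk100():
    return digital_disk(100)


@pytest.fixture
def tiny_large_cfg() -> SyntheticConfig:
    """Large-droplet preset shrunk to a handful of droplets/days."""
    return large_droplet_config(
        n_droplets=3,
        seed=11,
        contraction_schedule={2: 0.0, 6: 0.12},
        growth_curve={2: 60.0, 6: 290.0},
    )


@pytest.fixture
def tiny_small_cfg() -> SyntheticConfig:
    return small_droplet_config(
        n_droplets=3,
        seed=12,
        contraction_schedule={2: 0.0, 4: 0.02},
        growth_curve={2: 50.0, 4: 100.0},
    )
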