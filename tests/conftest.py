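import numpy as np
import pytest

from nodulecad import GeneratorConfig, generate_dataset


def make_disk(radius: int, pad: int = 4) -> np.ndarray:
    """Digital disk rasterized on a half-pixel-centered grid."""
    n = 2 * radius + 2 * pad
    yy, xx = np.mgrid[:n, :n]
    c = n / 2
    return (yy - c + 0.5) ** 2 + (xx - c + 0.5) ** 2 <= radius**2


def make_ellipse(a: int, b: int, angle_deg: float = 0.0, pad: int = 6) -> np.ndarray:
    n = 2 * max(a, b) + 2 * pad
    yy, xx = np.mgrid[:n, :n]
    c = n / 2
    t = np.deg2rad(angle_deg)
    xr = np.cos(t) * (xx - c + 0.5) + np.sin(t) * (yy - c + 0.5)
    yr = -np.sin(t) * (xx - c + 0.5) + np.cos(t) * (yy - c + 0.5)
    return (xr / a) ** 2 + (yr / b) ** 2 <= 1.0


@pytest.fixture(scope="session")
def small_dataset():
    """Small separable synthetic dataset shared across pipeline tests."""
    cfg = GeneratorConfig(n_nodule=30, n_nonnodule=24, seed=7,
                          class_separation=1.0)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def study_sized_dataset():
    """Full study-sized dataset (95 nodules / 75 non-nodules), separable."""
    return generate_dataset(GeneratorConfig(seed=11, class_separation=1.0))
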