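import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import morphodyn as m
from morphodyn.features import MaskClassifier
from morphodyn.shapes import synthetic_classes

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def small_config(**kinetic_overrides) -> m.SimulationConfig:
    """64x64 coarse grid for fast simulation tests."""
    cfg = m.SimulationConfig()
    cfg.grid.nx = cfg.grid.ny = 64
    cfg.grid.dx = 0.45
    cfg.grid.dt = 0.02
    for key, value in kinetic_overrides.items():
        setattr(cfg.kinetics, key, value)
    return cfg


@pytest.fixture
def quick_config() -> m.SimulationConfig:
    return small_config()


@pytest.fixture(scope="session")
def shape_dataset():
    """300 normalized masks in three separable classes (disk/hbar/vbar)."""
    return synthetic_classes(100, seed=0)


@pytest.fixture(scope="session")
def trained_classifier(shape_dataset):
    X, y = shape_dataset
    clf = MaskClassifier(epochs=30, seed=0)
    clf.fit(X, y)
    return clf


def disk_mask(radius: float, size: int = 128, cx: float | None = None,
              cy: float | None = None) -> np.ndarray:
    cy = size / 2 if cy is None else cy
    cx = size / 2 if cx is None else cx
    y, x = np.mgrid[:size, :size]
    return np.sqrt((x - cx) ** 2 + (y - cy) ** 2) <= radius


def tanh_disk(radius: float, size: int = 160, width: float = 2.0) -> np.ndarray:
    """Anti-aliased disk field whose 0.5 level set is truly circular."""
    y, x = np.mgrid[:size, :size]
    r = np.sqrt((x - size / 2) ** 2 + (y - size / 2) ** 2)
    return 0.5 * (1.0 - np.tanh((r - radius) / width))
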