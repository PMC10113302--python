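import numpy as np
import pytest

from vesselreg import MetricConfig, OptimizerConfig, make_bundle
from vesselreg.core import IntensityVolume, VesselForest, VesselSegment
from vesselreg.phantom import rasterize


@pytest.fixture(scope="session")
def bundle():
    """Standard depth-3 phantom bundle used across the suite."""
    return make_bundle(seed=1)


@pytest.fixture(scope="session")
def small_bundle():
    """Cheap depth-2 bundle (3 segments) for structural/driver tests."""
    return make_bundle(seed=3, depth=2)


@pytest.fixture(scope="session")
def desk_config():
    return OptimizerConfig.desk_scale()


@pytest.fixture(scope="session")
def fast_config():
    """Minimal-effort optimizer for structural checks where convergence
    quality does not matter (determinism, inheritance, traces)."""
    cfg = OptimizerConfig.desk_scale()
    cfg.powell_max_iter = 2
    cfg.grid_max_iter = 1
    return cfg


@pytest.fixture(scope="session")
def metric_config():
    return MetricConfig()


@pytest.fixture(scope="session")
def fast_metric():
    """Intensity-only metric (no gradient penalty) for structural checks
    where the objective's exact shape does not matter."""
    return MetricConfig(alpha2=0.0, n_rays=4)


def straight_tube_forest(
    direction=(0.0, 0.0, 1.0), radius=1.5, length=15.0, start=(0.0, 0.0, 0.0),
    n=21, seg_id=0,
):
    """Single straight vessel segment (helper, not a fixture)."""
    direction = np.asarray(direction, float)
    direction = direction / np.linalg.norm(direction)
    s = np.linspace(0.0, length, n)
    pos = np.asarray(start, float)[None, :] + s[:, None] * direction[None, :]
    seg = VesselSegment(id=seg_id, positions=pos, radii=np.full(n, radius))
    seg.represented = True
    return VesselForest(segments={seg_id: seg}, root_ids=[seg_id])


@pytest.fixture(scope="session")
def tube_volume():
    """Noiseless rasterized straight tube along z at coarse spacing."""
    forest = straight_tube_forest()
    return forest, rasterize(forest, 0.7)


def random_volume(rng, shape=(12, 14, 10)):
    return IntensityVolume(
        rng.random(shape),
        spacing=rng.uniform(0.3, 1.5, 3),
        origin=rng.uniform(-20, 20, 3),
    )
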