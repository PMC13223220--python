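import warnings

import numpy as np
import pytest

from rseikit.composite import compose_rsei
from rseikit.indices import compute_indices, normalize_indices
from rseikit.synthetic import SyntheticConfig, simulate


def small_config(**overrides) -> SyntheticConfig:
    defaults = dict(seed=5, grid_shape=(30, 100), years=tuple(range(2000, 2011)))
    defaults.update(overrides)
    return SyntheticConfig(**defaults)


def rsei_stack(scenes, mask):
    """Run the index + composite pipeline, suppressing range warnings."""
    results = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for scene in scenes:
            results.append(compose_rsei(normalize_indices(compute_indices(scene), mask), mask))
    return results


@pytest.fixture(scope="session")
def small_run():
    """A small default-structure synthetic run shared across test modules."""
    cfg = small_config()
    corridor, drivers, scenes, truth = simulate(cfg)
    return cfg, corridor, drivers, scenes, truth


@pytest.fixture(scope="session")
def small_rsei(small_run):
    cfg, corridor, drivers, scenes, truth = small_run
    results = rsei_stack(scenes, corridor.buffer_mask)
    return {r.year: r.rsei_layer for r in results}, results


@pytest.fixture(scope="session")
def noiseless_run():
    """Noise-free planted data: indices are exact monotone functions of q."""
    cfg = small_config(
        seed=9, noise_sd=0.0, monthly_noise_sd=0.0, index_disagreement_sd=0.0,
        years=tuple(range(2000, 2006)),
    )
    corridor, drivers, scenes, truth = simulate(cfg)
    return cfg, corridor, drivers, scenes, truth


@pytest.fixture(scope="session")
def small_samples(small_run, small_rsei):
    from rseikit.attribution import build_samples

    cfg, corridor, drivers, scenes, truth = small_run
    rsei_by_year, _ = small_rsei
    return build_samples(rsei_by_year, drivers, corridor)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
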