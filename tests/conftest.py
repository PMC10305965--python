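import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True,
                          database=None, deadline=None)
settings.load_profile("deterministic")

from eyecea import AnalysisConfig, pool_strategies
from eyecea.data_model import annualize_line
from eyecea.synthetic import GeneratorConfig, generate_provider_data


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture(scope="session")
def analysis_config():
    return AnalysisConfig()


def small_generator(seed: int, scale: float = 0.25, **kwargs) -> GeneratorConfig:
    """Default generator shrunk by ``scale`` in screening volume for speed."""
    cfg = GeneratorConfig(seed=seed, **kwargs)
    for params in cfg.strategies.values():
        params.screening_mean *= scale
    return cfg


def pooled_synthetic(seed: int, scale: float = 0.25, discount_rate: float = 0.03,
                     **kwargs):
    """Generate, annualize capital lines, and pool a synthetic dataset."""
    data = generate_provider_data(small_generator(seed, scale, **kwargs))
    datasets = []
    for _, d in data:
        lines = [annualize_line(l, discount_rate) for l in d.cost_lines]
        datasets.append(d.model_copy(update={"cost_lines": lines}))
    return pool_strategies(datasets)


@pytest.fixture(scope="session")
def pooled_default():
    """One pooled synthetic dataset at quarter volume, shared across tests."""
    return pooled_synthetic(seed=11)
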