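import numpy as np
import pytest

from ddifuse.data import PipelineConfig
from ddifuse.evaluation import build_drug_representation
from ddifuse.synth import SynthConfig, generate_dataset


@pytest.fixture(scope="session")
def bench_dataset():
    """The default synthetic benchmark (80 drugs, 4 groups, 5 types)."""
    return generate_dataset(SynthConfig())


@pytest.fixture(scope="session")
def small_config():
    return PipelineConfig.test_scale(seed=1)


@pytest.fixture(scope="session")
def bench_embedding(bench_dataset, small_config):
    """Unified embedding of the benchmark drugs through the full chain."""
    return build_drug_representation(bench_dataset, small_config, "nmdadnn")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
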