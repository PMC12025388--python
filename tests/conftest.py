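import numpy as np
import pytest

from catflex.synthetic import (
    GeneratorConfig,
    make_complex_template,
    make_ensemble,
)


@pytest.fixture(scope="session")
def generator_config() -> GeneratorConfig:
    return GeneratorConfig(seed=7)


@pytest.fixture(scope="session")
def base_complex(generator_config):
    return make_complex_template(generator_config, coordination_mode="major1")


@pytest.fixture(scope="session")
def small_ensemble(generator_config, base_complex):
    """30-conformer major1 ensemble with property table and truth record."""
    return make_ensemble(generator_config, base_complex, stream=1)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def synthetic_dataset(tmp_path_factory, generator_config):
    """Full on-disk dataset (5 coordination-mode groups, 8 conformers each)."""
    from catflex.synthetic import write_dataset
    from dataclasses import replace

    cfg = replace(generator_config, n_conformers=8)
    root = tmp_path_factory.mktemp("dataset")
    return write_dataset(root / "ds", cfg)
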