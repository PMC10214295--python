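import dataclasses

import numpy as np
import pytest

from gretarget import synthetic


@pytest.fixture(scope="session")
def small_cfg() -> synthetic.SyntheticConfig:
    """A compact universe for tests that only need structure, not power."""
    return synthetic.SyntheticConfig(
        n_genes=120, n_chroms=2, genome_span_bp=20_000_000,
        n_direct_targets=8, n_cells=12, n_random_oc=20, seed=5)


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    return synthetic.generate(small_cfg)


@pytest.fixture(scope="session")
def default_dataset():
    """The generator's default conditions (1000 genes, 50 planted targets, seed 17)."""
    return synthetic.generate(synthetic.SyntheticConfig())


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def vary(cfg, **kwargs):
    return dataclasses.replace(cfg, **kwargs)
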