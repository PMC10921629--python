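import numpy as np
import pytest

from hemorisk import deep_layers, panel_io
from hemorisk.deep_layers import EliminationConfig, SelectionConfig
from hemorisk.synthetic import GeneratorConfig, generate_panels


@pytest.fixture(scope="session")
def records_1k():
    """A seeded 1,000-record synthetic panel (default study conditions)."""
    return generate_panels(GeneratorConfig(n=1000, seed=101))


@pytest.fixture(scope="session")
def normalized_1k(records_1k):
    raw = panel_io.records_to_matrix(records_1k)
    norm, bounds = panel_io.min_max_normalize(raw)
    return norm, bounds


@pytest.fixture(scope="session")
def stats_1k(normalized_1k):
    return panel_io.analyte_stats(normalized_1k[0])


@pytest.fixture(scope="session")
def weighted_1k(normalized_1k, stats_1k):
    norm, _ = normalized_1k
    keep = deep_layers.eliminate_normal_records(norm, stats_1k, EliminationConfig())
    return deep_layers.self_weight(norm, stats_1k, keep)


@pytest.fixture(scope="session")
def training_set_1k(weighted_1k):
    ts, _ = deep_layers.select_by_interval(weighted_1k, SelectionConfig(i_t=50))
    return deep_layers.split_train_test(ts, fraction=0.75, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
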