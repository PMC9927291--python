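import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def three_tip_tree():
    from gcpanorama.tree import parse_newick
    return parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def yule_tree_50():
    from gcpanorama.synthetic_data import sim_yule_tree
    return sim_yule_tree(50, 1.0, seed=42)
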