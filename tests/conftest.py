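import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import phycosignal as ps

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def three_tip_tree():
    """((A:1,B:1):1,C:2); — the hand-computable workhorse."""
    return ps.parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def star_tree():
    """Equal-branch star: iid structure, K = 1 for any trait."""
    return ps.parse_newick("(A:1,B:1,C:1,D:1,E:1);")


@pytest.fixture(scope="session")
def yule59():
    return ps.generate_tree(59, seed=590)


@pytest.fixture(scope="session")
def yule50():
    return ps.generate_tree(50, seed=500)
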