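import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from karyoevol import read_counts, read_newick


@pytest.fixture
def three_tip_tree():
    return read_newick("((A:1,B:1):0.5,C:1.5);")


@pytest.fixture
def four_tip_tree():
    return read_newick("((A:0.3,B:0.6):0.4,(C:0.9,D:0.2):0.7);")


@pytest.fixture
def small_counts():
    return read_counts("A\t4\nB\t5\nC\t6")
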