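import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from prevratio import ContingencyTable2x2, reconstruct_table
from prevratio.datasets import CRUDE, PREVALENCE

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20231004)


@pytest.fixture(scope="session")
def marijuana_table():
    """Integer table consistent with the published marijuana crude row
    (n=5810, prevalence 9.6%, PR 3.493, se 0.2999), found by exhaustive
    reconstruction."""
    tables = reconstruct_table(5810, PREVALENCE["marijuana"],
                               CRUDE["marijuana"]["pr"],
                               CRUDE["marijuana"]["se"])
    assert ContingencyTable2x2(546, 4882, 11, 371) in tables
    return tables[0]


@pytest.fixture()
def simple_table():
    return ContingencyTable2x2(10, 90, 5, 95)
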