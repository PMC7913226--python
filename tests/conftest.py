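import pytest

from malnupbpk import build_psp_table, reference_individual
from malnupbpk.anthropometry import GrowthReference


@pytest.fixture(scope="session")
def ref_man():
    """The deterministic 30-year-old male reference individual."""
    return reference_individual(30.0, "male")


@pytest.fixture(scope="session")
def psp_table():
    return build_psp_table()


@pytest.fixture(scope="session")
def growth_ref():
    return GrowthReference.load()
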