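import pytest

from rippms import chem, ms_io, synth


@pytest.fixture(scope="session")
def dehydration():
    return chem.DEFAULT_MODIFICATIONS["dehydration"]


@pytest.fixture(scope="session")
def qqq():
    return ms_io.QQQ


@pytest.fixture(scope="session")
def two_state_run(dehydration):
    """A 60%-dehydrated synthetic run with realistic noise (seed 1)."""
    spec = synth.standard_two_state_run(0.6, seed=1)
    table, truth = synth.simulate_run(spec)
    return spec, table, truth
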