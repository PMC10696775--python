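import pytest

import cllcea


@pytest.fixture(scope="session")
def default_inputs():
    return cllcea.default_inputs()


@pytest.fixture()
def inputs(default_inputs):
    """A mutable copy of the packaged base case."""
    return default_inputs.copy()


@pytest.fixture(scope="session")
def base_traces(default_inputs):
    model = cllcea.CohortModel(default_inputs)
    return {arm: model.run(arm) for arm in ("ib", "beri")}


@pytest.fixture(scope="session")
def base_result(default_inputs):
    return cllcea.base_case(default_inputs)


@pytest.fixture(scope="session")
def psa_result(default_inputs):
    """The full 1000-draw probabilistic analysis at a fixed seed."""
    return cllcea.run_psa(default_inputs, n_draws=1000, seed=1)


@pytest.fixture(scope="session")
def tornado_entries(default_inputs):
    return cllcea.one_way_dsa(default_inputs)
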