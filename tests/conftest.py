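import pytest

from stepcea import generate_parameter_set


@pytest.fixture(scope="session")
def toy_params():
    return generate_parameter_set(42, "toy")


@pytest.fixture(scope="session")
def full_params():
    return generate_parameter_set(7, "full")


@pytest.fixture()
def toy_copy(toy_params):
    return toy_params.copy_deep()


@pytest.fixture(scope="session")
def quiet_params(toy_params):
    """Toy parameters with no events: zero rates, identity PA shift."""
    ps = toy_params.copy_deep()
    for lbl in ps.band_labels:
        ps.mortality[lbl] = 0.0
        for d in ("diabetes", "hypertension"):
            ps.incidence[lbl][d] = 0.0
            ps.complication_incidence[lbl][d] = 0.0
    ps.intervention_pa_shift = [[1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]]
    ps.control_pa_shift = [[1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]]
    return ps
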