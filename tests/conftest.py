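import pytest

import qscensus as qs


@pytest.fixture(scope="session")
def params():
    return qs.QSParameters.table1()


@pytest.fixture(scope="session")
def rate(params):
    return qs.calibrate_bare_rate(params)


@pytest.fixture(scope="session")
def profile(params):
    return qs.density_distribution(params)


@pytest.fixture(scope="session")
def srna_optimal(params):
    return qs.optimal_solution(params, "srna")


@pytest.fixture(scope="session")
def tf_optimal(params):
    return qs.optimal_solution(params, "tf")


@pytest.fixture(scope="session")
def srna_baseline(params):
    return qs.no_feedback_baseline(params, "srna")


@pytest.fixture(scope="session")
def tf_baseline(params):
    return qs.no_feedback_baseline(params, "tf")
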