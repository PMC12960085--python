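import pytest

import ventcost as vc


@pytest.fixture(scope="session")
def table1() -> vc.CohortTable:
    """The packaged 42-participant derivation cohort."""
    return vc.derivation_cohort()


@pytest.fixture(scope="session")
def table2():
    """The packaged 14-cyclist application summary."""
    return vc.application_table()


@pytest.fixture(scope="session")
def published() -> vc.CompositeCoefficients:
    return vc.published_composite()


@pytest.fixture(scope="session")
def table1_fit(table1):
    """Single full-cohort refit of the composite model, shared across tests."""
    return vc.fit_composite(table1)


@pytest.fixture(scope="session")
def table1_loocv(table1):
    """Leave-one-out cross-validation report on the derivation cohort."""
    return vc.loocv(table1)
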