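import pytest

from brainht import ParameterSet, run_treatment


@pytest.fixture(scope="session")
def defaults() -> ParameterSet:
    return ParameterSet()


@pytest.fixture(scope="session")
def functional_run(defaults):
    """Deterministic nominal run: fairly intact vasculature, 40 W/kg."""
    return run_treatment(
        defaults.replace(zeta=0.85, gamma=0.08), fluctuations_on=False
    )


@pytest.fixture(scope="session")
def impaired_run(defaults):
    """Deterministic nominal run: dysfunctional vasculature, 40 W/kg."""
    return run_treatment(
        defaults.replace(zeta=0.44, gamma=0.06), fluctuations_on=False
    )
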