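import pytest

from lupus_cea import AnalysisSettings, synthetic
from lupus_cea.pipeline import default_strategies


@pytest.fixture(scope="session")
def life_table():
    return synthetic.generate_life_table()


@pytest.fixture(scope="session")
def settings():
    return AnalysisSettings()


@pytest.fixture(scope="session")
def default_ledger():
    return synthetic.generate_default_ledger()


@pytest.fixture(scope="session")
def calibration(default_ledger, settings, life_table):
    return synthetic.calibrate_to_base_case(default_ledger, settings=settings,
                                            life_table=life_table)


@pytest.fixture(scope="session")
def calibrated_ledger(default_ledger, calibration):
    return default_ledger.with_values(calibration.values)


@pytest.fixture(scope="session")
def strategies(settings):
    return default_strategies(settings)
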