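import pandas as pd
import pytest

import aedespop as ap


@pytest.fixture(scope="session")
def params():
    return ap.MosquitoParams()


@pytest.fixture(scope="session")
def weather1():
    """One synthetic Mediterranean weather year."""
    return ap.generate_weather(seed=1, years=1)


@pytest.fixture(scope="session")
def weather4():
    """Four synthetic Mediterranean weather years (the study-period length)."""
    return ap.generate_weather(seed=1, years=4)


@pytest.fixture(scope="session")
def result4(weather4):
    """Default 4-year simulation (with spin-up) reused across tests."""
    return ap.AedesPopulationModel(weather4).simulate()


def make_result(df: pd.DataFrame) -> ap.SimulationResults:
    """Wrap a hand-built daily trajectory DataFrame as SimulationResults."""
    return ap.SimulationResults(df, params=None, config=None)
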