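import numpy as np
import pandas as pd
import pytest

from netsurv.lifetable import RateTable, gompertz_ratetable
from netsurv.scenarios import scenario_spec


@pytest.fixture(scope="session")
def rt_gompertz() -> RateTable:
    return gompertz_ratetable()


@pytest.fixture(scope="session")
def rt_zero() -> RateTable:
    """Rate table with no expected mortality (p* = 1 everywhere)."""
    return RateTable(p_star=np.ones((2, 111, 41)), age_min=0, year_min=1980)


@pytest.fixture(scope="session")
def rt_const() -> RateTable:
    """Constant p* = 0.98 everywhere."""
    return RateTable(p_star=np.full((2, 111, 41), 0.98), age_min=0, year_min=1980)


@pytest.fixture(scope="session")
def spec1():
    return scenario_spec(1)


@pytest.fixture(scope="session")
def spec2():
    return scenario_spec(2)


def make_cohort(times, events, age=70.0, sex=1, year=1995.5) -> pd.DataFrame:
    """Small hand-built patient table."""
    times = np.asarray(times, dtype=float)
    n = len(times)
    return pd.DataFrame(
        {
            "id": np.arange(n),
            "age_diag": np.broadcast_to(np.asarray(age, dtype=float), (n,)).copy(),
            "sex": np.broadcast_to(np.asarray(sex), (n,)).copy(),
            "year_diag": np.broadcast_to(np.asarray(year, dtype=float), (n,)).copy(),
            "time_years": times,
            "event": np.asarray(events, dtype=np.int64),
        }
    )
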