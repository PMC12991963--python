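import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import exclosure as ex

settings.register_profile(
    "suite",
    deadline=None,
    max_examples=40,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


SMALL_MONTHS = tuple(range(0, 19, 6))  # 4 occasions


@pytest.fixture(scope="session")
def tiny_null_survey() -> pd.DataFrame:
    """Two small sites, no treatment effects."""
    cfg = ex.scenario_preset(
        "null", sites=("S1", "S2"), n_pairs=3, months=SMALL_MONTHS,
        pool_size=25, seed=11,
    )
    return ex.simulate_survey(cfg)


@pytest.fixture(scope="session")
def small_homog_survey() -> pd.DataFrame:
    """One site, homogenization scenario, reduced scale but full time span."""
    cfg = ex.scenario_preset(
        "homogenization", sites=("S1",), n_pairs=6,
        months=tuple(range(0, 91, 18)) + (156,), pool_size=60, seed=21,
    )
    return ex.simulate_survey(cfg)
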