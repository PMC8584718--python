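import pandas as pd
import pytest

from temppop import synthetic_data as sd
from temppop.data_model import Month, months_of_year


@pytest.fixture(scope="session")
def months_2018() -> list[Month]:
    return months_of_year(2018)


@pytest.fixture(scope="session")
def default_scenario() -> sd.Scenario:
    """The standard 20-region scenario, built once per session."""
    return sd.build_scenario(sd.ScenarioConfig(seed=20180101))


@pytest.fixture()
def toy_regions() -> pd.DataFrame:
    """Two regions sharing a climate but differing in remoteness."""
    return pd.DataFrame(
        {
            "region_id": ["A1", "B2"],
            "region_name": ["Alpha", "Beta"],
            "climate_zone": ["Warm summer, cool winter"] * 2,
            "remoteness_class": ["Major Cities", "Remote"],
        }
    )
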