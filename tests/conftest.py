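import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from basinopt import Basin, SynthConfig, generate_basin, hotspot_fixture

settings.register_profile("repeatable", derandomize=True, deadline=None)
settings.load_profile("repeatable")


@pytest.fixture
def chain3() -> Basin:
    """Three catchments in a chain c1 -> c2 -> c3 with one point source at the top."""
    df = pd.DataFrame(
        {
            "id": ["c1", "c2", "c3"],
            "region_id": ["r1", "r1", "r1"],
            "downstream_id": ["c2", "c3", None],
            "src_manure": [0.0, 0.0, 0.0],
            "src_mineral": [0.0, 0.0, 0.0],
            "src_point": [10.0, 0.0, 0.0],
            "src_scattered": [0.0, 0.0, 0.0],
            "basin_retention": [0.2, 0.2, 0.2],
            "river_retention": [0.5, 0.5, 0.0],
            "discharge_Mm3": [1.0, 2.0, 4.0],
        }
    )
    return Basin(df)


@pytest.fixture
def mixed_chain3() -> Basin:
    """Chain with all four sectors populated and nonzero retentions."""
    df = pd.DataFrame(
        {
            "id": ["a", "b", "c"],
            "region_id": ["r1", "r1", "r2"],
            "downstream_id": ["b", "c", None],
            "src_manure": [4.0, 1.0, 2.0],
            "src_mineral": [3.0, 0.5, 1.0],
            "src_point": [2.0, 0.0, 5.0],
            "src_scattered": [1.0, 0.5, 0.5],
            "basin_retention": [0.3, 0.4, 0.2],
            "river_retention": [0.2, 0.1, 0.05],
            "discharge_Mm3": [1.5, 3.0, 6.0],
        }
    )
    return Basin(df)


@pytest.fixture
def small_basin() -> Basin:
    return generate_basin(SynthConfig(n_catchments=20, n_regions=2, seed=11))


@pytest.fixture(scope="session")
def hotspot() -> Basin:
    return hotspot_fixture()
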