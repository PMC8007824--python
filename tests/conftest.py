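import pandas as pd
import pytest

from methylomap.io_formats import ProteomeDB
from methylomap.synthetic_data import SimConfig, simulate


@pytest.fixture
def tiny_proteome() -> ProteomeDB:
    return ProteomeDB(
        {
            "P1": "MAAARGGF",
            "P2": "RGGAY",
            "P3": "MAGRARAKLMRN",
        }
    )


@pytest.fixture
def site_table() -> pd.DataFrame:
    """hnRNPA1-style toy site table: five regulated MMA sites in the RGG
    repeat region, one unchanged site on another protein."""
    rows = []
    for pos in (194, 206, 218, 225, 232):
        rows.append(
            {
                "protein": "hnRNPA1",
                "position": pos,
                "methyl_type": "MMA",
                "intensity_L": 1000.0,
                "intensity_H": 500.0,
            }
        )
    rows.append(
        {
            "protein": "OTHER1",
            "position": 10,
            "methyl_type": "MMA",
            "intensity_L": 1000.0,
            "intensity_H": 950.0,
        }
    )
    return pd.DataFrame(rows)


@pytest.fixture
def protein_table() -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"protein": "hnRNPA1", "intensity_L": 5e5, "intensity_H": 5e5},
            {"protein": "OTHER1", "intensity_L": 2e5, "intensity_H": 2e5},
        ]
    )


@pytest.fixture(scope="session")
def default_sim():
    """One default-condition simulation shared across read-only tests."""
    return simulate(SimConfig(seed=11))
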