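import logging

import numpy as np
import pandas as pd
import pytest

from fdgradient import (
    CoverMatrix,
    SimConfig,
    TraitMeta,
    TraitTable,
    generate,
)

logging.getLogger("fdgradient").setLevel(logging.WARNING)


@pytest.fixture(scope="session")
def default_dataset():
    """One study-scale synthetic dataset (6 transects x 20 plots, 40 species)."""
    return generate(SimConfig(seed=11))


def make_cover(cover_dict, site_types=None, positions=None):
    """Build a small CoverMatrix from {plot: {species: cover}}."""
    df = pd.DataFrame(cover_dict).T.fillna(0.0).astype(float)
    n = len(df)
    meta = pd.DataFrame(
        {
            "transect_id": ["T1"] * n,
            "site_type": site_types or ["type_A"] * n,
            "position_index": positions or list(range(n)),
        },
        index=df.index,
    )
    return CoverMatrix(df, meta)


@pytest.fixture
def tiny_cover():
    return make_cover(
        {
            "p1": {"foc": 50.0, "s1": 30.0, "s2": 10.0, "s3": 10.0},
            "p2": {"foc": 20.0, "s1": 10.0, "s2": 40.0, "s3": 30.0},
        }
    )


@pytest.fixture
def tiny_traits():
    return TraitTable(
        pd.DataFrame({"H": [0.1, 0.5, 0.9]}, index=["s1", "s2", "s3"]),
        {"H": TraitMeta("continuous", "m")},
    )
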