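import numpy as np
import pandas as pd
import pytest

from rasbiofilter import datasets


@pytest.fixture
def uwm_params():
    """Model parameters configured for the study biofilter."""
    return datasets.uwm_model_params()


@pytest.fixture
def uwm_geometry():
    return datasets.uwm_geometry()


@pytest.fixture
def depth_marker_table():
    """Published depth-mean qPCR values as a three-sample long table."""
    return datasets.uwm_depth_marker_table()


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture
def small_marker_table():
    """Tiny hand-built long marker table: 2 assays x 4 samples."""
    rows = []
    vals = {"a": [10.0, 20.0, 30.0, 40.0], "b": [1.0, 3.0, 2.0, 4.0]}
    for assay, series in vals.items():
        for i, v in enumerate(series):
            rows.append(
                {
                    "assay": assay,
                    "sample_id": f"s{i}",
                    "day": 7.0 * i,
                    "depth": "surface",
                    "cn_per_g": v,
                    "sd": 0.0,
                }
            )
    return pd.DataFrame(rows)
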