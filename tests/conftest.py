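import numpy as np
import pandas as pd
import pytest

from neurofuse.cohort import BlockSpec, simulate_feature_table
from neurofuse.table import FeatureTable


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_table():
    """108-subject, 3-site, 3-group table with planted multimodal effects."""
    table, gt = simulate_feature_table(n_per_group_per_site=12, seed=11)
    return table, gt


@pytest.fixture
def toy_table():
    """Hand-built 8-subject table for arithmetic-level checks."""
    ids = pd.Index([f"s{i}" for i in range(8)], name="subject_id")
    values = pd.DataFrame({
        "CogA total": [4.0, 6.0, 5.0, 7.0, 3.0, 5.0, 4.0, 6.0],
        "EF total": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0],
    }, index=ids)
    modality = pd.Series({"CogA total": "NPS", "EF total": "NPS"})
    site = pd.Series(["A", "A", "A", "A", "B", "B", "B", "B"], index=ids)
    group = pd.Series(["HC", "HC", "bvFTD", "bvFTD"] * 2, index=ids)
    return FeatureTable(values, modality, site, group)


@pytest.fixture
def noise_block():
    """Block factory for tables without any group effect."""
    def make(n_features, modality="NPS"):
        return {modality: BlockSpec(modality, n_features, 0)}
    return make
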