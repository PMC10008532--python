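import warnings

import numpy as np
import pandas as pd
import pytest

from spikeline import detect, simulate
from spikeline.model import CountTable


@pytest.fixture(scope="session")
def small_experiment():
    """A small replicated two-mass × three-dose experiment."""
    cfg = simulate.study_design_config(seed=7, replicates=2, depth=20_000, n_taxa=100)
    return simulate.simulate_experiment(cfg)


@pytest.fixture(scope="session")
def small_assignment(small_experiment):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return detect.assign_mc_svs(
            small_experiment.sequences,
            small_experiment.config.references,
            small_experiment.table,
        )


@pytest.fixture
def toy_table():
    """3 samples × 3 SVs with easy hand-checkable totals."""
    return CountTable(
        pd.DataFrame(
            [[5, 3, 2], [10, 0, 10], [1, 1, 1]],
            index=["s1", "s2", "s3"],
            columns=["sv1", "sv2", "sv3"],
        )
    )


@pytest.fixture
def toy_metadata():
    return pd.DataFrame(
        {
            "sample_id": ["s1", "s2", "s3"],
            "biomass_mass": [50.0, 50.0, 1.25],
            "mc_dose_fraction": [0.5, 0.5, 0.0],
            "pool_id": ["P1", "P1", "P2"],
        }
    )
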