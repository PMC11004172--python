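import numpy as np
import pandas as pd
import pytest

from leukoflow.alot_synth import SimConfig, simulate_cohort
from leukoflow.vocab import DIAGNOSES


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_cohort(tmp_path_factory):
    """A small on-disk cohort: 2 patients per diagnosis, 400 events each."""
    out = tmp_path_factory.mktemp("tiny_cohort")
    config = SimConfig(
        n_patients_per_diagnosis={d: 2 for d in DIAGNOSES},
        n_events=400,
        seed=7,
    )
    manifest_path = simulate_cohort(config, out)
    return pd.read_csv(manifest_path, dtype=str)
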