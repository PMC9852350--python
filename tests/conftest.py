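import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from xenotraffic import RunConfig, pipeline
from xenotraffic.synthetic_data import SimulationConfig


@pytest.fixture
def run_config():
    return RunConfig()


@pytest.fixture
def small_sim_config():
    """A quick-to-generate dataset that still exercises every class."""
    return SimulationConfig(n_host_genes=300, n_parasite_genes=300, seed=11)


@pytest.fixture(scope="session")
def sweep_reports():
    """Full-pipeline reports for the default study conditions over ten
    seeds; shared by the recovery, mediation and sanity-check tests."""
    return {
        seed: pipeline.run_synthetic(SimulationConfig(seed=seed),
                                     with_enrichment=False)
        for seed in range(10)
    }


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
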