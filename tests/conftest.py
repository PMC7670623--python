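import dataclasses

import numpy as np
import pandas as pd
import pytest

from methresp.containers import MethylationMatrix
from methresp.simulate import SimulationConfig, simulate_beta, simulate_cohort, simulate_manifest


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A fast cohort: 40 subjects, 1500 probes, mild noise, planted effects."""
    return dataclasses.replace(
        SimulationConfig(),
        n_subjects=40,
        n_probes=1500,
        n_planted_dmrs=4,
        n_planted_ewas_cpgs=5,
        markers_per_cell_type=30,
        noise_sd=0.05,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    manifest = simulate_manifest(small_config)
    cohort = simulate_cohort(small_config)
    matrix, detection, truth = simulate_beta(manifest, cohort, small_config)
    return manifest, cohort, matrix, truth


@pytest.fixture()
def toy_matrix() -> MethylationMatrix:
    beta = pd.DataFrame(
        {"s1": [0.1, 0.2, 0.3], "s2": [0.2, 0.4, 0.6]},
        index=["cg1", "cg2", "cg3"],
    )
    return MethylationMatrix(beta)


def rng_for(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)
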