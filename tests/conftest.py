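"""Shared fixtures: small simulated cohorts and the packaged catalogs."""

import numpy as np
import pytest

from metaconcord import datasets
from metaconcord.synthetic_data import DEFAULT_GENOME, SimulationConfig, simulate_cohort

#: Small genome for fast segmentation-heavy tests.
SMALL_GENOME = [(c, length, 150) for c, length, _ in DEFAULT_GENOME]


@pytest.fixture(scope="session")
def small_cohort():
    """Four pairs on a reduced probe grid, default study conditions."""
    return simulate_cohort(
        SimulationConfig(n_pairs=4, genome=SMALL_GENOME, seed=11)
    )


@pytest.fixture(scope="session")
def high_trunk_cohort():
    """Eight pairs dominated by truncal events (trunk fraction 0.9, low
    probe noise): the regime where paired best-match structure is
    expected."""
    return simulate_cohort(
        SimulationConfig(
            n_pairs=8,
            genome=SMALL_GENOME,
            trunk_share_prob=0.9,
            private_mut_rate_primary=0.3,
            private_mut_rate_metastasis=0.3,
            cna_event_rate=6.0,
            probe_noise_sd=0.1,
            seed=7,
        )
    )


@pytest.fixture(scope="session")
def catalog():
    return datasets.load_recurrence_catalog()


@pytest.fixture(scope="session")
def gene_regions():
    return datasets.load_gene_regions()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
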