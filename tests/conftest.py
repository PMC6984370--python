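import numpy as np
import pytest

from novoseqkit.synthetic_cohort import SimConfig, simulate_cohort


def small_sim_config(**overrides) -> SimConfig:
    """A fast cohort configuration for unit tests (not the study-scale
    defaults, which the acceptance tests use)."""
    kwargs = dict(
        seed=11,
        n_individuals=20,
        n_ns=30,
        ref_length=200_000,
        ns_length_range=(301, 4_000),
        n_ur_per_individual=200,
        n_decoys_per_individual=3,
        n_small_per_individual=3,
        n_contaminants=2,
        contaminant_len_range=(22_701, 30_000),
    )
    kwargs.update(overrides)
    return SimConfig(**kwargs)


@pytest.fixture(scope="session")
def small_cohort():
    return simulate_cohort(small_sim_config())


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_dna(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))
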