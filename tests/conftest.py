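"""Shared fixtures: small simulated cohorts reused across test modules."""
import numpy as np
import pytest

from exochip.caller import joint_call
from exochip.simchip import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_clean_sim():
    """A clean 200-sample x 300-variant cohort with pedigree structure."""
    cfg = SimConfig(
        n_samples=200,
        n_variants=300,
        n_trios=5,
        n_replicate_pairs=5,
        seed=101,
    )
    return cfg, *simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_clean_calls(small_clean_sim):
    """Joint-called genotypes for the small clean cohort."""
    _, intensities, truth = small_clean_sim
    calls, scores, cluster_file = joint_call(
        intensities,
        truth.sample_meta["sex"].to_numpy(),
        truth.variant_meta["chrom_class"].to_numpy(),
    )
    return calls, scores, cluster_file


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
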