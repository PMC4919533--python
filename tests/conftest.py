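import numpy as np
import pytest

from convmap.synth import SyntheticConfig, generate_dataset, make_design


@pytest.fixture(scope="session")
def small_design():
    """6 associations, 1 instance, 1 run -> 12 retrieval + 12 ITI labels."""
    return make_design(n_associations=6, instances_per_condition=1, runs=1)


@pytest.fixture(scope="session")
def full_design():
    """The full study design: 96 retrieval + 96 ITI labels."""
    return make_design(n_associations=12, instances_per_condition=2, runs=2)


@pytest.fixture(scope="session")
def tiny_dataset():
    """3 subjects, 10^3 grid, planted conjunctive + hub effects."""
    cfg = SyntheticConfig(
        grid_shape=(10, 10, 10), n_regions=4, n_modules=2, n_subjects=3,
        n_associations=6, instances_per_condition=1, runs=2,
        conjunctive_effect=1.5, hub_effect=1.5, noise_sd=1.0,
        planted_region_id=1, seed=42)
    subjects, gt = generate_dataset(cfg)
    return cfg, subjects, gt


@pytest.fixture(scope="session")
def null_dataset():
    """Global-null twin of tiny_dataset (all effects zero)."""
    cfg = SyntheticConfig(
        grid_shape=(10, 10, 10), n_regions=4, n_modules=2, n_subjects=3,
        n_associations=6, instances_per_condition=1, runs=2,
        noise_sd=1.0, planted_region_id=1, seed=42)
    subjects, gt = generate_dataset(cfg)
    return cfg, subjects, gt


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
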