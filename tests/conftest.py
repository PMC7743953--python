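import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20201216)


@pytest.fixture(scope="session")
def tiny_study():
    """Small complete synthetic study shared across tests."""
    from equigen.simulate import (
        CompetitionSimConfig,
        GenotypeSimConfig,
        PedigreeSimConfig,
        StudyConfig,
        simulate_study,
    )

    cfg = StudyConfig(
        seed=42,
        pedigree=PedigreeSimConfig(n_founders=40, n_generations=2, n_per_generation=120),
        n_measured=120,
        n_genotyped=80,
        n_events=8,
        genotypes=GenotypeSimConfig(n_snps=300),
        competition=CompetitionSimConfig(years=(2015, 2016), starts_per_horse_year=2),
    )
    return simulate_study(cfg)
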