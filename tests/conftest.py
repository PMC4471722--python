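import pytest
from hypothesis import settings

from chromosurvey import synthio

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_chromosome():
    """A 60 kb synthetic chromosome at the default study conditions
    (85% repetitive, planted genes and miRNA precursors), shared across
    tests that only read it."""
    config = synthio.GenerationConfig(
        length=60_000, repeat_fraction=0.85, n_genes=4, n_mirna_loci=3, seed=11
    )
    sequence, truth = synthio.generate_chromosome(config)
    return config, sequence, truth


@pytest.fixture()
def default_chromosome():
    """A fresh default-condition chromosome (mutable truth per test)."""
    config = synthio.GenerationConfig(
        length=120_000, repeat_fraction=0.85, n_genes=8, n_mirna_loci=4, seed=23
    )
    sequence, truth = synthio.generate_chromosome(config)
    return config, sequence, truth
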