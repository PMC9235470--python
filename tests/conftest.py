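import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from mrsketch.seqkmer import HashOrder, SequenceRecord


@pytest.fixture(scope="session")
def order():
    return HashOrder(seed=7)


@pytest.fixture
def worked_example():
    """The single-sequence dataset whose 3-mers are AAT, ATA, TAA, AAG."""
    return [SequenceRecord("g1", "AATAAG")]


@pytest.fixture(scope="session")
def genome_pair():
    """A 5 kb random genome and a 3%-diverged descendant."""
    from mrsketch.synthdata import generate_genome, mutate_genome

    parent = generate_genome(5000, seed=11, genome_id="parent")
    child = mutate_genome(parent, divergence=0.03, seed=12, genome_id="child")
    return parent, child
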