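import pytest
from hypothesis import HealthCheck, settings

from plastome import synth

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_genome():
    """Default miniature plastome (seed 1) with its ground truth."""
    return synth.generate_plastome(seed=1)


@pytest.fixture(scope="session")
def default_transcripts(default_genome):
    genome, truth = default_genome
    by_gene, edits = synth.generate_transcripts(genome, truth, coverage=5,
                                                edit_fraction=1.0)
    return by_gene, edits
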