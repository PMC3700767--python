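import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hiddenstops import GeneticCode, SyntheticSpec, Transcript, Transcriptome, generate_organism

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def code() -> GeneticCode:
    return GeneticCode.standard()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230622)


@pytest.fixture(scope="session")
def small_organism() -> Transcriptome:
    """A modest synthetic transcriptome (GC 0.5, no injection) for reuse."""
    return generate_organism(
        SyntheticSpec(
            organism_id="fixture_org",
            gc_target=0.5,
            n_transcripts=50,
            length_codons=100,
            seed=11,
        )
    )


@pytest.fixture
def random_transcriptome(rng) -> Transcriptome:
    sense = GeneticCode.standard().sense_codons
    transcripts = [
        Transcript(
            id=f"r{i}",
            seq="".join(sense[j] for j in rng.integers(0, len(sense), size=100)),
        )
        for i in range(10)
    ]
    return Transcriptome(organism_id="rand", transcripts=transcripts)
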