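import numpy as np
import pytest

from markermine.synthetic_data import (
    SimulationConfig,
    SSRPlant,
    simulate_reads,
    simulate_transcripts,
)


def random_dna(rng: np.random.Generator, length: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(list(alphabet), size=length))


@pytest.fixture(scope="session")
def small_sim():
    """A 20-transcript simulation with planted SSRs, ORFs and variants,
    shared by the recovery-style tests."""
    cfg = SimulationConfig(
        n_transcripts=20,
        ssr_plants=[SSRPlant("ACC", 5), SSRPlant("CA", 5), SSRPlant("GATC", 3)],
        orf_fraction=0.5,
        auto_variants_per_transcript=1,
        minor_fraction_range=(0.3, 0.5),
        coverage_target=40.0,
        seed=11,
    )
    transcripts, truth = simulate_transcripts(cfg)
    reads, alignments = simulate_reads(transcripts, truth, cfg)
    return cfg, transcripts, truth, reads, alignments
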