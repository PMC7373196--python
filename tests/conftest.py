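import numpy as np
import pytest

from dcscan.genome import Genome
from dcscan.simulate import SimulationConfig, generate_genome


@pytest.fixture(scope="session")
def small_genome() -> Genome:
    """A 50 kb random genome at E. coli-like GC content."""
    return generate_genome(50_000, 0.508, seed=42)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def mixed_locus_plan() -> list[dict]:
    """20 loci cycling through all four architectures."""
    archs = ["divergent5", "convergent3", "full_overlap", "novel_as"]
    return [
        {
            "architecture": archs[i % 4],
            "overlap_length": 150 + 10 * (i % 5),
            "abundance": 40,
        }
        for i in range(20)
    ]


@pytest.fixture(scope="session")
def mixed_sim_config(mixed_locus_plan) -> SimulationConfig:
    return SimulationConfig(
        genome_length=40_000,
        locus_plan=mixed_locus_plan,
        digestion_mode="mn",
        noise_read_count=0,
        seed=2024,
    )
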