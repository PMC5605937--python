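import numpy as np
import pytest

from lambdaint.sequence_io import Genome
from lambdaint.synthetic import (
    SimulationConfig,
    default_motif_matrix,
    generate_genome,
    plant_sites,
    simulate_library,
)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def toy_genome():
    # 60 nt, no repeats of length >= 12
    seq = "ACGTACGGTTAGCCATTGACCTGAGTCAAGGCTTACGATCGGATACCTAGCATGGAACTG"
    return Genome(name="toy", sequence=seq, circular=True)


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """A small error-free simulated library shared across tests."""
    cfg = SimulationConfig(
        genome_length=30_000,
        n_secondary_sites=8,
        secondary_read_fraction=0.05,
        n_replicates=3,
        reads_per_replicate=1_000,
        seed=11,
    )
    genome = generate_genome(cfg)
    genome, manifest = plant_sites(genome, default_motif_matrix(), cfg)
    out = tmp_path_factory.mktemp("small_sim")
    paths = simulate_library(genome, manifest, cfg, out)
    return cfg, genome, manifest, paths


def random_genome(rng, length, gc=0.5):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join("ACGT"[c] for c in rng.choice(4, size=length, p=p))
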