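import pytest

from fldseg.synthgen import (
    SimConfig,
    align_reads,
    segments_as_contigs,
    simulate_flds_reads,
    simulate_genomes,
)


@pytest.fixture(scope="session")
def sim3():
    """A small simulated study: 3 bisegmented genomes, 50x, 0.2% errors."""
    cfg = SimConfig(n_genomes=3, seed=11)
    genomes = simulate_genomes(cfg)
    reads, truth = simulate_flds_reads(genomes, cfg)
    return cfg, genomes, reads, truth


@pytest.fixture(scope="session")
def sim3_aligned(sim3):
    cfg, genomes, reads, truth = sim3
    contigs = segments_as_contigs(genomes)
    alignments = align_reads(reads, truth, contigs)
    return cfg, genomes, contigs, alignments
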