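import numpy as np
import pytest

from exotarget import SimConfig, run_pipeline
from exotarget.genomics import Feature, GenomeAnnotation, GenomeSequence


@pytest.fixture(scope="session")
def default_config() -> SimConfig:
    return SimConfig(seed=1)


@pytest.fixture(scope="session")
def default_run(default_config):
    """One full pipeline run at the default study conditions (shared)."""
    return run_pipeline(default_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def toy_genome():
    """A deterministic 2-gene toy genome for unit tests."""
    rng = np.random.default_rng(7)
    seq = "".join("ACGT"[b] for b in rng.integers(0, 4, 3000))
    genome = GenomeSequence({"chr1": seq})
    plus = Feature.build("geneA", "mRNA", "chr1", "+", [(100, 300), (400, 600), (700, 900)])
    minus = Feature.build("geneB", "ncRNA", "chr1", "-", [(1200, 1500)])
    annotation = GenomeAnnotation([plus, minus], genome.chrom_lengths)
    return genome, annotation
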