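import numpy as np
import pytest

from frameshift_scan.codons import SENSE_CODONS, CodingSequence
from frameshift_scan.synthetic_data import SimulationConfig, generate_cds_set


def random_cds(rng: np.random.Generator, n_codons: int | None = None, id: str = "cds") -> CodingSequence:
    """Independent random valid ORF: ATG + random sense codons + stop."""
    if n_codons is None:
        n_codons = int(rng.integers(10, 60))
    body = rng.choice(np.array(SENSE_CODONS, dtype=object), size=n_codons - 2)
    stop = ["TAA", "TAG", "TGA"][int(rng.integers(3))]
    return CodingSequence(id=id, seq="ATG" + "".join(body) + stop)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Reduced stalling scenario for fast unit tests."""
    return SimulationConfig(seed=7, n_genes=30, reads_per_gene=300)


@pytest.fixture(scope="session")
def small_cds_set(small_config):
    return generate_cds_set(small_config, small_config.streams()["cds"])
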