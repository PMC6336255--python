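import pytest

from lncflow.genome_io import GenomicInterval, TranscriptModel
from lncflow.simulate import SimulationConfig, simulate_study


def make_tx(tid, chrom, start, end, strand="+", category="assembled", gene=None):
    """Single-exon transcript helper for geometry tests."""
    return TranscriptModel(
        tid,
        gene or f"gene_{tid}",
        (GenomicInterval(chrom, start, end, strand),),
        category,
    )


@pytest.fixture(scope="session")
def default_study():
    """The standard synthetic study (NB noise, dispersion 0.1)."""
    return simulate_study(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def noiseless_study():
    """Zero-noise limit: counts are the rounded planted means."""
    return simulate_study(SimulationConfig(seed=11, exact_counts=True))
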