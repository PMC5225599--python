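import pytest

from rnam5c.synthetic_data import SimulationConfig, generate_transcriptome


@pytest.fixture(scope="session")
def small_st():
    """Small transcriptome with hairpin-carrying transcripts."""
    cfg = SimulationConfig(seed=11, n_genes=6, hairpin_fraction=0.5, cds_mean=200)
    return generate_transcriptome(cfg)


@pytest.fixture(scope="session")
def plain_st():
    """Plain transcriptome without designed structure tails."""
    cfg = SimulationConfig(seed=7, n_genes=10, hairpin_fraction=0.0)
    return generate_transcriptome(cfg)
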