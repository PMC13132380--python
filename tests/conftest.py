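import pandas as pd
import pytest

from bivalstate import (
    GenomeAnnotation,
    SimulationConfig,
    make_promoters,
    simulate_chip,
    simulate_genome,
)


@pytest.fixture
def tiny_annotation() -> GenomeAnnotation:
    return GenomeAnnotation(
        pd.DataFrame(
            {
                "gene_id": ["gA", "gB", "gC"],
                "chrom": ["chr1", "chr1", "chr2"],
                "strand": ["+", "-", "+"],
                "tss": [1000, 8000, 500],
                "biotype": ["protein_coding", "protein_coding", "lncRNA"],
            }
        )
    )


@pytest.fixture
def tiny_promoters(tiny_annotation):
    return make_promoters(tiny_annotation)


@pytest.fixture(scope="session")
def noisefree_simulation():
    """1,000 genes, 30% planted bivalent, zero noise: the oracle genome."""
    ann = simulate_genome(1000, seed=1)
    cfg = SimulationConfig(n_genes=1000, noise_sigma=0.0, seed=1)
    return ann, cfg, simulate_chip(ann, cfg)
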