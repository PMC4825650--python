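import numpy as np
import pytest
from hypothesis import settings

import parentdiff as pdx

settings.register_profile("suite", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def trio():
    """Small genome trio shared by read-only tests."""
    cfg = pdx.SimulationConfig(seed=101, n_chromosomes=4,
                               chromosome_length=60_000, n_genes=24,
                               mean_cds_length=200)
    return pdx.generate_genome_trio(cfg)


@pytest.fixture(scope="session")
def coding_rich_trio():
    """Trio with dense coding variation for classification/dN-dS oracles."""
    cfg = pdx.SimulationConfig(seed=202, n_chromosomes=2,
                               chromosome_length=100_000, n_genes=40,
                               mean_cds_length=300,
                               mutation_rate_parent1=0.01,
                               mutation_rate_parent2=0.008,
                               coding_rate_scale=1.0,
                               hemi_snp_fraction=0.0)
    return pdx.generate_genome_trio(cfg)


def make_call(chrom="A01", pos=0, ref="A", alt="G", quality=40.0, depth=20,
              af=1.0, pnr=0.99, parent="parent1"):
    return pdx.VariantCall(chromosome=chrom, position=pos, ref_allele=ref,
                           alt_allele=alt, quality=quality, depth=depth,
                           alt_frequency=af, prob_not_ref=pnr, parent=parent)


@pytest.fixture
def call_factory():
    return make_call
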