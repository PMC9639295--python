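import numpy as np
import pandas as pd
import pytest

from reqtlkit.simulate import (
    SimConfig,
    generate_expression,
    generate_footprints,
    generate_gene_models,
    generate_genotypes,
)


def small_config(**overrides) -> SimConfig:
    """Desk-scale cohort used across tests: 60 lines, 800 variants, 160 genes."""
    base = dict(
        n_samples=60,
        n_chromosomes=2,
        chrom_length_bp=2_000_000,
        n_variants=800,
        n_genes=160,
        n_trans_hotspots=1,
        targets_per_hotspot=12,
        n_hidden_factors=2,
        seed=20240915,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def sim_config():
    return small_config()


@pytest.fixture(scope="session")
def cohort(sim_config):
    """(G, genes, pair, truth, footprints) for the shared small cohort."""
    G = generate_genotypes(sim_config)
    genes = generate_gene_models(sim_config)
    pair, truth = generate_expression(G, genes, sim_config)
    fp = generate_footprints(truth, genes, G, sim_config)
    return G, genes, pair, truth, fp


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(7)
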