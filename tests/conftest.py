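import numpy as np
import pytest

from plastevo.synthetic import SimulationConfig, simulate_clade, simulate_plastome


@pytest.fixture(scope="session")
def small_sim():
    """A desk-scale quadripartite plastome with planted SSRs."""
    config = SimulationConfig(
        seed=11,
        lsc_len=9000,
        ssc_len=700,
        ir_len=2200,
        n_genes_lsc=6,
        n_genes_ir=2,
        gene_len_codons=(80, 160),
        ssr_plan=(
            ("A", 10, "lsc"),
            ("AT", 7, "lsc"),
            ("ACT", 5, "ssc"),
            ("ATTTGTACA", 3, "ira"),
        ),
    )
    record, truth = simulate_plastome(config)
    return config, record, truth


@pytest.fixture(scope="session")
def fullsize_sim():
    """A plastome at the dimensions of a strongly SSC-contracted
    epidendroid genome (85,994 / 608 / 37,024 bp)."""
    config = SimulationConfig(seed=7, n_genes_lsc=12, n_genes_ir=4)
    record, truth = simulate_plastome(config)
    return config, record, truth


@pytest.fixture(scope="session")
def clade_sim():
    """Three related genomes evolved from one ancestor."""
    config = SimulationConfig(
        seed=21,
        lsc_len=6000,
        ssc_len=600,
        ir_len=1600,
        n_genes_lsc=5,
        n_genes_ir=2,
        gene_len_codons=(60, 120),
        tree="((Alpha_one:0.02,Alpha_two:0.02):0.015,Beta_one:0.035);",
        omega=0.2,
        ssr_plan=(("A", 11, "lsc"), ("AT", 8, "lsc")),
    )
    records, truth = simulate_clade(config)
    return config, records, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
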