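import numpy as np
import pandas as pd
import pytest

from crosstrait.synthetic_data import (
    SimulationConfig,
    make_ld_panel,
    table1_fixture,
)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        m_snps=300, ld_block_size=20, ld_decay=0.9, n_ref=400,
        n1_cases=10_000, n1_controls=10_000, n2_cases=5_000, n2_controls=5_000,
        h2_1=0.1, h2_2=0.25, rg=0.4, seed=42,
    )


@pytest.fixture(scope="session")
def small_panel(small_config):
    return make_ld_panel(small_config)


@pytest.fixture(scope="session")
def risk_table():
    return table1_fixture()


@pytest.fixture
def toy_sumstats_frame():
    """Three well-formed rows in the canonical layout."""
    return pd.DataFrame({
        "SNP": ["rs1", "rs2", "rs3"],
        "CHR": ["1", "1", "2"],
        "BP": [1000, 2000, 3000],
        "A1": ["A", "C", "G"],
        "A2": ["G", "T", "A"],
        "BETA": [0.1, -0.05, 0.02],
        "SE": [0.05, 0.05, 0.01],
        "Z": [2.0, -1.0, 2.0],
        "P": [0.04550026389635842, 0.31731050786291415, 0.04550026389635842],
        "N_CAS": [1000, 1000, 1000],
        "N_CON": [2000, 2000, 2000],
        "MAF": [0.2, 0.3, 0.4],
        "INFO": [0.99, 0.95, 0.97],
    })


def _toy_panel(genotypes: np.ndarray, block_bounds=None):
    """Panel wrapper around an explicit dosage matrix (one block by default)."""
    from crosstrait.sumstats_io import VariantRecord
    from crosstrait.synthetic_data import LDPanel

    m = genotypes.shape[1]
    variants = [
        VariantRecord(f"rs{j + 1}", "1", 1 + j * 1000, "A", "G", maf=0.3, info=1.0)
        for j in range(m)
    ]
    return LDPanel(variants=variants, genotypes=np.asarray(genotypes, dtype=float),
                   block_bounds=block_bounds or [(0, m)])


@pytest.fixture
def toy_panel_factory():
    return _toy_panel
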