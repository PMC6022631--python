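import numpy as np
import pytest

from hybridasm.synthetic_data import SimParams, simulate_transcriptome


@pytest.fixture(scope="session")
def small_transcriptome():
    """20 multi-isoform genes with shared exons, fixed seed."""
    params = SimParams(n_genes=20, isoforms_per_gene=(1, 3), seed=42)
    genes, truth = simulate_transcriptome(params)
    return params, genes, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
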