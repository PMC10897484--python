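import numpy as np
import pandas as pd
import pytest

from cnpop import GenotypeMatrix, SimulationConfig, simulate_dataset


def make_loci(n, length=5000, chrom="chr1"):
    return pd.DataFrame({
        "id": [f"L{i + 1}" for i in range(n)],
        "chrom": chrom,
        "start": np.arange(n) * 1_000_000,
        "end": np.arange(n) * 1_000_000 + length,
    })


def matrix_from_cn(cn, populations, confidence=None, loci=None):
    """GenotypeMatrix from a raw CN array and per-sample population labels."""
    cn = np.asarray(cn)
    loci = make_loci(cn.shape[0]) if loci is None else loci
    samples = [f"S{i + 1}" for i in range(cn.shape[1])]
    return GenotypeMatrix(loci, samples, populations, cn, confidence)


@pytest.fixture(scope="session")
def three_pop_dataset():
    """Three well-differentiated populations (used by clustering tests)."""
    cfg = SimulationConfig(
        n_populations=3, n_individuals=40, n_loci=200, F=0.15,
        architecture_mix=(0.6, 0.2, 0.2), seed=11,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def two_pop_dataset():
    """Two moderately differentiated populations of deletion loci."""
    cfg = SimulationConfig(
        n_populations=2, n_individuals=50, n_loci=300, F=0.05,
        architecture_mix=(1.0, 0.0, 0.0), seed=5,
    )
    return simulate_dataset(cfg)
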