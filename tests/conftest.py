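import numpy as np
import pandas as pd
import pytest

from xresponse.annotations_io import CountMatrix, GenomeAnnotation
from xresponse.synthetic import SimulationConfig, simulate_bundle


@pytest.fixture
def tiny_annotation() -> GenomeAnnotation:
    """Three chromosomes, hand-placed genes, X-like chromosome included."""
    genes = pd.DataFrame(
        [
            ("a1", "chr1", 100, 1100, "+", 1000),
            ("a2", "chr1", 5000, 7000, "-", 2000),
            ("a3", "chr1", 9000, 9500, "+", 500),
            ("b1", "chr2", 200, 1200, "+", 1000),
            ("b2", "chr2", 3000, 3600, "-", 600),
            ("x1", "chrX", 100, 2100, "+", 2000),
            ("XIST", "chrX", 5000, 8000, "-", 3000),
        ],
        columns=["gene_id", "chrom", "start", "end", "strand", "length"],
    )
    return GenomeAnnotation(
        genes=genes, chrom_lengths={"chr1": 10_000, "chr2": 10_000, "chrX": 10_000}
    )


@pytest.fixture
def small_counts() -> CountMatrix:
    rng = np.random.default_rng(11)
    genes = [f"g{i}" for i in range(50)]
    counts = pd.DataFrame(
        rng.poisson(100, size=(50, 6)),
        index=genes,
        columns=[f"c{i}" for i in range(3)] + [f"d{i}" for i in range(3)],
    )
    meta = pd.DataFrame(
        {"condition": ["control"] * 3 + ["deficient"] * 3, "replicate": [1, 2, 3, 1, 2, 3]},
        index=counts.columns,
    )
    return CountMatrix(counts=counts, sample_meta=meta)


@pytest.fixture(scope="session")
def stem_study():
    """One full synthetic study under the default (stem) conditions."""
    return simulate_bundle(SimulationConfig(seed=20))


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A reduced genome for fast per-module tests."""
    return SimulationConfig(seed=5, n_autosomes=3, autosome_length=20_000_000, x_length=30_000_000)
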